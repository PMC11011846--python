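>bsa synthetic stand-in; Trp=2 Tyr=20 Cys=35; alanine filler
AAAAAAAAAAWAAAAAAAAAAWAAAAAAAAAAYAAAAAAAAAAYAAAAAAAAAAYAAAAA
AAAAAYAAAAAAAAAAYAAAAAAAAAAYAAAAAAAAAAYAAAAAAAAAAYAAAAAAAAAA
YAAAAAAAAAAYAAAAAAAAAAYAAAAAAAAAYAAAAAAAAAYAAAAAAAAAYAAAAAAA
AAYAAAAAAAAAYAAAAAAAAAYAAAAAAAAAYAAAAAAAAAYAAAAAAAAAYAAAAAAA
AACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAA
AACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAA
AACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAA
AACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAA
AACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAA
AACAAAAAAAAACAAAAAAAAACAAAAAAAAACAAAAAAAAAC
>ovalbumin synthetic stand-in; Trp=3 Tyr=10 Cys=6; alanine filler
AAAAAAAAAAAAAAAAAAAAWAAAAAAAAAAAAAAAAAAAAWAAAAAAAAAAAAAAAAAA
AAWAAAAAAAAAAAAAAAAAAAAYAAAAAAAAAAAAAAAAAAAAYAAAAAAAAAAAAAAA
AAAAYAAAAAAAAAAAAAAAAAAAYAAAAAAAAAAAAAAAAAAAYAAAAAAAAAAAAAAA
AAAAYAAAAAAAAAAAAAAAAAAAYAAAAAAAAAAAAAAAAAAAYAAAAAAAAAAAAAAA
AAAAYAAAAAAAAAAAAAAAAAAAYAAAAAAAAAAAAAAAAAAACAAAAAAAAAAAAAAA
AAAACAAAAAAAAAAAAAAAAAAACAAAAAAAAAAAAAAAAAAACAAAAAAAAAAAAAAA
AAAACAAAAAAAAAAAAAAAAAAAC
>conalbumin synthetic stand-in; Trp=9 Tyr=21 Cys=30; alanine filler
AAAAAAAAAAAWAAAAAAAAAAAWAAAAAAAAAAAWAAAAAAAAAAAWAAAAAAAAAAAW
AAAAAAAAAAAWAAAAAAAAAAAWAAAAAAAAAAAWAAAAAAAAAAAWAAAAAAAAAAAY
AAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAY
AAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAY
AAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAY
AAAAAAAAAAAYAAAAAAAAAAYAAAAAAAAAAYAAAAAAAAAAYAAAAAAAAAAYAAAA
AAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAA
ACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAA
AAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAA
AACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAA
AAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAAAAACAAAAAAA
AAACAAAAAAAAAACAAAAAAAAAAC
>trastuzumab synthetic stand-in; Trp=22 Tyr=54 Cys=32; alanine filler
AAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAA
AAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAA
AAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAA
AWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAA
AAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAYA
AAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAA
AAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAA
AAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAA
AAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAA
AAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAA
AAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAA
AAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAA
AAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAA
AAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAA
AAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAA
AAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAACAAAA
AAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAA
AAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAA
AAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAA
AAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAA
AAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAA
AAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAA
AAAAAAAC
>pertuzumab synthetic stand-in; Trp=21 Tyr=54 Cys=32; alanine filler
AAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAA
AAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAA
AAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAA
AWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAA
AAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAWAAAAAAAAAAAAYAAAAAAAAAAAAYA
AAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAA
AAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAA
AAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAA
YAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAA
AAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAA
AAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAA
AAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAA
AAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAA
AAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAA
AAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAA
AAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAAYAAAAAAAAAAACAAAAAAAA
AAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAA
AAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAA
AAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAA
AAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAA
AAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAA
AAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAACAAAAAAAA
AAAC
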