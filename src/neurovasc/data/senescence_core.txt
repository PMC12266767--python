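# Convenience core senescence gene list (mouse symbols): CDK inhibitors,
# p53 axis, and common SASP factors. Any user-supplied list (e.g. SenMayo)
# can be used in its place.
Cdkn2a
Cdkn1a
Cdkn2b
Trp53
Serpine1
Glb1
Il6
Il1a
Il1b
Cxcl1
Cxcl2
Ccl2
Ccl5
Ccl8
Ccl20
Mmp3
Mmp9
Mmp12
Timp1
Igfbp3
Igfbp7
Tnf
Nfkb1
Hmgb1
Vegfa
Serpine2
Plau
Plaur
Icam1
Tgfb1
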