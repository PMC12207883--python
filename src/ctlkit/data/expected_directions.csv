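marker,expected,marker_class
PD-1,up,primary
CTLA-4,up,primary
LAG-3,up,primary
TIGIT,up,primary
TCF-1,down,primary
CXCR5,down,secondary
Ki67,down,secondary
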