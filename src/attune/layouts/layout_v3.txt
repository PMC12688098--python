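XXPXXXXXXXPXX
XX1..X....2.X
XXX..X......B
O....G......X
B....X.XXXXXX
X....X......X
XDXXXXXXXOXDX
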