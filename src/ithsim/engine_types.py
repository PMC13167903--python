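"""Shared lattice constants."""

# Moore neighborhood offsets (8 surrounding sites), fixed order.
MOORE = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
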