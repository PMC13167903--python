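# Melanoma driver genes with hallmark tags.
# Tags: p = proliferation, q = survival, r = genetic instability,
#       c = decreased antigenicity (immune evasion), c~ = increased antigenicity.
# The exclusive_group lists loci (BRAF, NRAS, KIT) of which at most one may
# ever be mutated in a single cell.
drivers:
  - {index: 0, name: BRAF, tags: [c, p, q]}
  - {index: 1, name: NRAS, tags: [p]}
  - {index: 2, name: KIT, tags: [p]}
  - {index: 3, name: TERT, tags: [q]}
  - {index: 4, name: CDKN2A, tags: [p]}
  - {index: 5, name: MITF, tags: [q]}
  - {index: 6, name: PTEN, tags: [q, r]}
exclusive_group: [0, 1, 2]
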