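# Reticulation model 2 (approximate schematic rendering): one hybridization
# event whose donor is an ancestral (internal) population.  Species tree
# (((2,3),(4,5)),1); taxon 3 receives 40% of its genome from the common
# ancestor of taxa 4 and 5.  Internal branches: ILS index 0.368 (Ne = 1e5).
taxa: ["1", "2", "3", "4", "5"]
ne: 1.0e5
joins:
  - {time: 500000, children: ["4", "5"], parent: "a45"}
  - {time: 1000000, children: ["2", "3"], parent: "a23"}
  - {time: 1099967, children: ["a23", "a45"], parent: "a2345"}
  - {time: 2099967, children: ["a2345", "1"], parent: "root"}
hybrids:
  - {time: 1000000, recipient: "3", donor: "a45", proportion: 0.4}
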