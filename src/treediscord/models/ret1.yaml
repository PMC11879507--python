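# Reticulation model 1 (approximate schematic rendering): one hybridization
# event, tip recipient, distant tip donor.  Species tree ((((2,3),4),5),1);
# taxon 3 receives 40% of its genome from taxon 5's lineage.  Every internal
# branch is -ln(0.368) * Ne = 99967 generations long (ILS index 0.368).
taxa: ["1", "2", "3", "4", "5"]
ne: 1.0e5
joins:
  - {time: 1000000, children: ["2", "3"], parent: "a23"}
  - {time: 1099967, children: ["a23", "4"], parent: "a234"}
  - {time: 1199934, children: ["a234", "5"], parent: "a2345"}
  - {time: 2199934, children: ["a2345", "1"], parent: "root"}
hybrids:
  - {time: 1000000, recipient: "3", donor: "5", proportion: 0.4}
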