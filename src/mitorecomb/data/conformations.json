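{
  "C_carlesii": {
    "repeat_copies": {
      "LR9": [[["contig7", "-"], ["contig4", "-"]], [["contig2", "+"], ["contig8", "+"]]],
      "LR10": [[["contig6", "-"], ["contig3", "-"]], [["contig2", "-"], ["contig7", "-"]]],
      "LR11": [[["contig5", "-"], ["contig1", "-"]], [["contig12", "-"], ["contig8", "-"]]]
    },
    "direct_links": [[["contig5", "+"], ["contig3", "+"]], [["contig6", "+"], ["contig4", "+"]]],
    "molecules": [
      {"path": "contig1-LR11-contig5-contig3-LR10-contig6-contig4-LR9-contig7-LR10-contig2-LR9-contig8-LR11-contig12", "topology": "linear"}
    ]
  },
  "Ca_henryi": {
    "repeat_copies": {
      "LR7": [[["contig1", "+"], ["contig5", "+"]], [["contig5", "+"], ["contig1", "+"]]],
      "LR8": [[["contig2", "+"], ["contig4", "+"]], [["contig3", "+"], ["contig3", "+"]]],
      "LR9": [[["contig4", "+"], ["contig6", "+"]], [["contig6", "+"], ["contig2", "+"]]]
    },
    "direct_links": [],
    "molecules": [
      {"path": "contig1-LR7-contig5-LR7", "topology": "circular"},
      {"path": "contig4-LR9-contig6-LR9-contig2-LR8", "topology": "circular"},
      {"path": "contig3-LR8", "topology": "circular"}
    ]
  }
}
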