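{
 "biallelic_genes": [
  "gene0000",
  "gene0001",
  "gene0004",
  "gene0006",
  "gene0007",
  "gene0008",
  "gene0009",
  "gene0010",
  "gene0011",
  "gene0012",
  "gene0013",
  "gene0014",
  "gene0015",
  "gene0017",
  "gene0021",
  "gene0022",
  "gene0023",
  "gene0024",
  "gene0027",
  "gene0029",
  "gene0032",
  "gene0033",
  "gene0034",
  "gene0035",
  "gene0038",
  "gene0039",
  "gene0041",
  "gene0043",
  "gene0044",
  "gene0046",
  "gene0047",
  "gene0048",
  "gene0051",
  "gene0052",
  "gene0053",
  "gene0056",
  "gene0057",
  "gene0058",
  "gene0061",
  "gene0064",
  "gene0067",
  "gene0071",
  "gene0073",
  "gene0076",
  "gene0078",
  "gene0079",
  "gene0081",
  "gene0084",
  "gene0085",
  "gene0086",
  "gene0087",
  "gene0090",
  "gene0091",
  "gene0093",
  "gene0094",
  "gene0099"
 ],
 "escapees": [
  "gene0027",
  "gene0032",
  "gene0052",
  "gene0079",
  "gene0084",
  "gene0085"
 ],
 "fraction_reactivated": {
  "1": {
   "D5": 0.2727272727272727,
   "ESC": 1.0,
   "NPC": 0.0,
   "iPSC": 1.0
  },
  "2": {
   "D5": 0.631578947368421,
   "ESC": 1.0,
   "NPC": 0.15789473684210525,
   "iPSC": 1.0
  },
  "3": {
   "D5": 0.6153846153846154,
   "ESC": 1.0,
   "NPC": 0.07692307692307693,
   "iPSC": 1.0
  },
  "4": {
   "D5": 0.5454545454545454,
   "ESC": 1.0,
   "NPC": 0.18181818181818182,
   "iPSC": 1.0
  }
 },
 "funnel": {
  "expressed": 57,
  "input": 100,
  "snp_informative": 75
 },
 "promoter_accessibility": {
  "gene0000": 0.0,
  "gene0001": 0.0,
  "gene0004": 0.0,
  "gene0006": 0.0,
  "gene0007": 0.0,
  "gene0008": 0.0,
  "gene0009": 0.0,
  "gene0010": 0.0,
  "gene0011": 0.0,
  "gene0012": 0.0,
  "gene0013": 0.0,
  "gene0014": 0.0,
  "gene0015": 0.0,
  "gene0017": 0.0,
  "gene0021": 0.0,
  "gene0022": 0.0,
  "gene0023": 0.0,
  "gene0024": 0.0,
  "gene0027": 0.0,
  "gene0029": 0.0,
  "gene0032": 0.0,
  "gene0033": 0.0,
  "gene0034": 0.0,
  "gene0035": 0.0,
  "gene0038": 0.0,
  "gene0039": 0.0,
  "gene0041": 0.0,
  "gene0043": 0.0,
  "gene0044": 0.0,
  "gene0046": 1425.0,
  "gene0047": 0.0,
  "gene0048": 0.0,
  "gene0051": 0.0,
  "gene0052": 0.0,
  "gene0053": 0.0,
  "gene0056": 0.0,
  "gene0057": 0.0,
  "gene0058": 0.0,
  "gene0061": 1500.0,
  "gene0064": 0.0,
  "gene0067": 0.0,
  "gene0071": 0.0,
  "gene0073": 0.0,
  "gene0076": 0.0,
  "gene0078": 0.0,
  "gene0079": 0.0,
  "gene0081": 0.0,
  "gene0084": 0.0,
  "gene0085": 0.0,
  "gene0086": 0.0,
  "gene0087": 0.0,
  "gene0090": 0.0,
  "gene0091": 0.0,
  "gene0092": 0.0,
  "gene0093": 0.0,
  "gene0094": 0.0,
  "gene0099": 0.0
 },
 "reactivation_time": {
  "gene0000": "iPSC",
  "gene0001": "D5",
  "gene0004": "D5",
  "gene0006": "D5",
  "gene0007": "iPSC",
  "gene0008": "D5",
  "gene0009": "D5",
  "gene0010": "D5",
  "gene0011": "D5",
  "gene0012": "iPSC",
  "gene0013": "D5",
  "gene0014": "D5",
  "gene0015": "iPSC",
  "gene0017": "iPSC",
  "gene0021": "D5",
  "gene0022": "iPSC",
  "gene0023": "D5",
  "gene0024": "iPSC",
  "gene0027": "NPC",
  "gene0029": "D5",
  "gene0032": "NPC",
  "gene0033": "D5",
  "gene0034": "iPSC",
  "gene0035": "iPSC",
  "gene0038": "iPSC",
  "gene0039": "iPSC",
  "gene0041": "D5",
  "gene0043": "D5",
  "gene0044": "iPSC",
  "gene0046": "iPSC",
  "gene0047": "D5",
  "gene0048": "iPSC",
  "gene0051": "iPSC",
  "gene0052": "NPC",
  "gene0053": "D5",
  "gene0056": "iPSC",
  "gene0057": "iPSC",
  "gene0058": "D5",
  "gene0061": "iPSC",
  "gene0064": "D5",
  "gene0067": "iPSC",
  "gene0071": "iPSC",
  "gene0073": "iPSC",
  "gene0076": "D5",
  "gene0078": "D5",
  "gene0079": "NPC",
  "gene0081": "D5",
  "gene0084": "NPC",
  "gene0085": "NPC",
  "gene0086": "iPSC",
  "gene0087": "iPSC",
  "gene0090": "iPSC",
  "gene0091": "D5",
  "gene0093": "iPSC",
  "gene0094": "D5",
  "gene0099": "iPSC"
 },
 "relative_differential_peaks": {
  "1": {
   "D5": 0.29411764705882354,
   "ESC": 1.0,
   "NPC": 0.0,
   "iPSC": 0.6470588235294118
  },
  "2": {
   "D5": 0.3333333333333333,
   "ESC": 1.0,
   "NPC": 0.0,
   "iPSC": 0.6666666666666666
  },
  "3": {
   "D5": 0.30434782608695654,
   "ESC": 1.0,
   "NPC": 0.0,
   "iPSC": 0.6521739130434783
  },
  "4": {
   "D5": 0.3125,
   "ESC": 1.0,
   "NPC": 0.0,
   "iPSC": 0.625
  }
 },
 "seed": 23
}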