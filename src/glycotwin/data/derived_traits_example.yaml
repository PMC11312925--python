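# Illustrative derived-trait definitions for a small synthetic O-glycopeptide
# panel on the hinge-region peptide HYT.  Real analyses supply their own
# published per-site formula set in this schema; weighted sums use
# denominator "1".
traits:
  - name: HYT_frac_sialylated
    peptide: HYT
    numerator:
      HYT_H3N5F0S1: 1.0
      HYT_H3N5F0S2: 1.0
    denominator:
      HYT_H3N5F0S0: 1.0
      HYT_H3N5F0S1: 1.0
      HYT_H3N5F0S2: 1.0
  - name: HYT_sial_per_glycoform
    peptide: HYT
    numerator:
      HYT_H3N5F0S1: 1.0
      HYT_H3N5F0S2: 2.0
    denominator:
      HYT_H3N5F0S0: 1.0
      HYT_H3N5F0S1: 1.0
      HYT_H3N5F0S2: 1.0
  - name: HYT_sialylated_sum
    peptide: HYT
    numerator:
      HYT_H3N5F0S1: 1.0
      HYT_H3N5F0S2: 1.0
    denominator: "1"
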