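# Median AUC0-t (ng.h/mL, 95% CI) after a 155 mg base dose, as reported by the
# published PK-Sim HCQ model for virtual healthy, Child-Pugh cirrhosis, and CKD
# populations.  These are evaluation-layer inputs for percent-change arithmetic,
# not simulation parameters.
iv:
  healthy:      {median: 5317, ci_low: 5142, ci_high: 5532}
  CP-A:         {median: 7096, ci_low: 6465, ci_high: 7528}
  CP-B:         {median: 8176, ci_low: 7772, ci_high: 8650}
  CP-C:         {median: 9204, ci_low: 8645, ci_high: 9709}
  CKD-moderate: {median: 5187, ci_low: 4904, ci_high: 5519}
  CKD-severe:   {median: 5088, ci_low: 4665, ci_high: 5466}
oral:
  healthy:      {median: 4989, ci_low: 4812, ci_high: 5245}
  CP-A:         {median: 6966, ci_low: 6488, ci_high: 7600}
  CP-B:         {median: 7961, ci_low: 7171, ci_high: 8600}
  CP-C:         {median: 8735, ci_low: 8449, ci_high: 9632}
  CKD-moderate: {median: 4890, ci_low: 4539, ci_high: 5235}
  CKD-severe:   {median: 4961, ci_low: 4603, ci_high: 5342}
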