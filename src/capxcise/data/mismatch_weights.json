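{
  "description": "Per-position mismatch penalties for SpCas9 off-target weighting. Index 1 is the PAM-distal end of the 20-nt protospacer, index 20 is PAM-proximal. An off-target site's weight is the product of (1 - penalty) over its mismatched positions; penalties rise toward the PAM because seed mismatches disrupt cleavage most.",
  "penalties": [0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
                0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583]
}
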