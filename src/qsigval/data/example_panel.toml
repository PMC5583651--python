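# SYNTHETIC EXAMPLE panel configuration.
#
# Gene identities, roles and QC thresholds match the deployed 12-gene assay;
# the score coefficients, intercept and clinical-score weights below are
# SYNTHETIC placeholders for demonstration and testing -- the published
# signature's coefficient values are proprietary and never printed.

[genes]
targets = ["AZGP1", "BIRC5", "DHCR7", "IL6ST", "MGP", "RBBP8", "STC2", "UBE2C"]
housekeepers = ["CALM2", "OAZ1", "RPL37A"]
contamination = "HBB"

[score]
intercept = 5.1
clip = [0.0, 15.0]

[score.coefficients]
# sign convention: normalized expression = HKM - Ct (higher = more expressed);
# proliferation-associated genes carry positive weight, protective genes negative
AZGP1 = -0.25
BIRC5 = 0.45
DHCR7 = 0.30
IL6ST = -0.35
MGP = -0.20
RBBP8 = -0.30
STC2 = -0.40
UBE2C = 0.50

[qc]
hkm_range = [19.0, 27.0]
contamination_ct_cutoff = 38.0
contamination_min_replicates = 2

[risk]
low_max = 3.3
high_min = 3.4

[clinical]
w_molecular = 0.5
w_size = 1.0
w_nodes = 0.1
intercept = 0.0
node_cap = 10

[clinical.size_codes]
# ordinal tumor-size categories (pT-like coding)
"1" = 1.0
"2" = 2.0
"3" = 3.0
"4" = 4.0
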