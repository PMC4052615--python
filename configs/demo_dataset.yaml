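# Demo study: one binary feature (ER), 100 samples per status.
# Six sign-change pairs, two strong fold-change pairs, four null pairs;
# several pairs also carry mean shifts so the DE stage has signal.
n_status1: 100
n_status2: 100
feature: ER
seed: 11
pairs:
  - {mirna: hsa-miR-101, mrna: GENE01, healthy_sign: D, rho_status1: 0.7,  rho_status2: -0.7, delta_mirna: 1.5,  delta_mrna: -1.5}
  - {mirna: hsa-miR-102, mrna: GENE02, healthy_sign: D, rho_status1: 0.7,  rho_status2: -0.7, delta_mirna: -1.5, delta_mrna: 1.5}
  - {mirna: hsa-miR-103, mrna: GENE03, healthy_sign: D, rho_status1: -0.7, rho_status2: 0.7}
  - {mirna: hsa-miR-104, mrna: GENE04, healthy_sign: U, rho_status1: 0.7,  rho_status2: -0.7, delta_mirna: 1.5,  delta_mrna: 1.5}
  - {mirna: hsa-miR-105, mrna: GENE05, healthy_sign: U, rho_status1: -0.7, rho_status2: 0.7}
  - {mirna: hsa-miR-106, mrna: GENE06, healthy_sign: D, rho_status1: 0.7,  rho_status2: -0.7}
  - {mirna: hsa-miR-107, mrna: GENE07, healthy_sign: D, rho_status1: 0.85, rho_status2: 0.15, delta_mirna: 1.5, delta_mrna: -1.5}
  - {mirna: hsa-miR-108, mrna: GENE08, healthy_sign: D, rho_status1: -0.15, rho_status2: -0.85}
  - {mirna: hsa-miR-109, mrna: GENE09, healthy_sign: D, rho_status1: 0.1,  rho_status2: 0.1}
  - {mirna: hsa-miR-110, mrna: GENE10, healthy_sign: U, rho_status1: -0.1, rho_status2: -0.1}
  - {mirna: hsa-miR-111, mrna: GENE11, healthy_sign: D, rho_status1: 0.0,  rho_status2: 0.0,  delta_mirna: 1.5}
  - {mirna: hsa-miR-112, mrna: GENE12, healthy_sign: D, rho_status1: 0.3,  rho_status2: 0.3}
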