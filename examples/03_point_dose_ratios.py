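"""Point-dose ratio statistics for a synthetic IMRT/VMAT patient cohort.

Generates 40 patients whose planning-system doses carry a +2.2% bias on
VMAT and -0.2% on IMRT relative to the ion chamber, then prints the
TPS/IC, VS/IC and TPS/VS summary table (Total / VMAT / IMRT).
"""

import beamcheck as bc

records = bc.make_point_dose_cohort(
    n=40, bias_tps=(-0.002, 0.022), bias_vs=(-0.002, 0.015),
    sd_tps=0.015, sd_vs=0.009, sd_ic=0.005, vmat_fraction=0.3, seed=1)

print(f"{'group':14s} {'TPS/IC':>13s} {'VS/IC':>13s} {'TPS/VS':>13s}")
for s in bc.aggregate_ratios(records):
    print(f"{s.group_label:14s} "
          f"{s.mean_tps_ic:6.1f}±{s.sd_tps_ic:<5.1f} "
          f"{s.mean_vs_ic:6.1f}±{s.sd_vs_ic:<5.1f} "
          f"{s.mean_tps_vs:6.1f}±{s.sd_tps_vs:<5.1f}")
# Ratios are percent; 100 means perfect agreement with the chamber.
# The VMAT rows sit ~2% hot by construction, the IMRT rows near 100.
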