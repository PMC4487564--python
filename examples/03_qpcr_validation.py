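"""Validate a candidate deletion by simulated TaqMan qPCR.

Builds a 48 vs 48 plate in which 30 of 48 cases carry a heterozygous
deletion (relative dose 0.5) at the target locus, estimates per-sample
copy numbers by the comparative-CT rule cn = 2 * 2^(-ddCT), and compares
the groups with the chi-square (on integer-rounded copy classes) and
Mann-Whitney U tests.
"""

import pandas as pd

import cghscreen as cg
from cghscreen.synthetic_data import simulate_qpcr_plate

doses = pd.DataFrame(
    [
        {"sample": f"case_{i:02d}", "group": "case", "region": "striatum",
         "assay": "candidate_locus", "dose": 0.5 if i <= 30 else 1.0}
        for i in range(1, 49)
    ]
    + [
        {"sample": f"ctrl_{i:02d}", "group": "control", "region": "striatum",
         "assay": "candidate_locus", "dose": 1.0}
        for i in range(1, 49)
    ]
)
plate = simulate_qpcr_plate(doses, ct0=26.0, sigma_ct=0.08, replicates=4, seed=3)
print(f"plate: {len(plate)} wells "
      f"({plate['assay'].nunique()} assays x 96 samples x 4 replicates)")

cn = cg.sample_copy_numbers(plate, "candidate_locus")
print("\nper-group copy-number summary:")
print(cn.groupby("group")["cn"].describe()[["count", "mean", "50%", "std"]]
      .round(3).to_string())

res = cg.group_compare(cn[["group", "cn"]])
print("\ninteger copy-number classes (rounded half away from zero):")
print(res["contingency"].to_string())
print(f"\nchi-square p = {res['chi2_p']:.3g}")
print(f"Mann-Whitney U p = {res['mwu_p']:.3g}")
print("\nBoth tests reject: carriers cluster at one copy while controls")
print("sit at two, so the dosage difference seen on the arrays is")
print("confirmed by an independent quantification chemistry.")
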