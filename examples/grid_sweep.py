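"""Training-period grid sweep over a synthetic cohort.

Evaluates every scan pair of a 20-virtual-patient cohort in both
directions over the modeling-period grid T_M in {5, 10, 15, 25, 35} s and
correction-period grid T_C in {5, 10, 15} s (with T_C <= T_M), corrected
and uncorrected, and prints the per-cell median 3D RMSE.  The medians
plateau once both training periods exceed ~10 s — one breathing cycle for
most patients.
"""

import respsurro as rs

members = rs.simulate_cohort(20, seed=0)
long_df, summary, n_failures = rs.grid_sweep(
    [m.pair for m in members], anchor="scan_b"
)
print(f"{len(long_df)} estimations, {n_failures} failed cells\n")

print("uncorrected: T_M (s) -> median 3D RMSE (mm)")
unc = summary[~summary["corrected"]]
for _, row in unc.iterrows():
    print(f"  T_M={row.t_m_s:4.0f}            median {row.median_mm:6.2f} "
          f"(IQR {row.q25_mm:.2f}-{row.q75_mm:.2f})")

print("\ncorrected (scan-B anchor): (T_M, T_C) -> median 3D RMSE (mm)")
cor = summary[summary["corrected"]]
for _, row in cor.iterrows():
    print(f"  T_M={row.t_m_s:4.0f} T_C={row.t_c_s:4.0f}  median {row.median_mm:6.2f} "
          f"(IQR {row.q25_mm:.2f}-{row.q75_mm:.2f})")
print("\nBaseline-drift correction collapses the inter-scan error; the residual")
print("medians change little beyond T_M = T_C = 10 s (the plateau).")
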