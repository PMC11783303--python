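"""Contingency analysis of positive-selection counts.

Recomputes, from the per-model counts of genes with signatures of positive
selection (1,005 nonimmune control genes vs 977 immune genes), the
likelihood-ratio chi-square for each detection model and the range of
immune:control rate ratios.
"""

from immusel import stats as st

ROWS = {
    "PAML M1a vs M2a (nominal)": (142, 307),
    "PAML M1a vs M2a (q<0.2)": (138, 305),
    "BUSTED -S -MH (nominal)": (201, 356),
    "BUSTED -S -MH (q<0.2)": (218, 363),
    "BUSTED model-average (nominal)": (89, 127),
    "BUSTED model-average (q<0.2)": (20, 37),
}
N_CONTROL, N_IMMUNE = 1005, 977

for label, (kc, ki) in ROWS.items():
    g, df, p = st.two_by_two_lrt(kc, N_CONTROL, ki, N_IMMUNE)
    print(f"{label:34s} chi2 = {g:6.2f} (df={df}), p = {p:.2g}")

ratios = [(kc, N_CONTROL, ki, N_IMMUNE) for kc, ki in ROWS.values()]
lo, hi = st.proportion_ratio_range(ratios)
print(f"\nimmune genes show {lo} to {hi} times the control rate of "
      "positive selection across detection models")
# The drop in chi-square from the simple models (~86) to the
# model-averaged rows (~6-9) reflects how accounting for synonymous-rate
# variation and multi-hit substitutions shrinks the number of significant
# genes in both groups.
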