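"""qPCR knockdown quantification and F2 segregation statistics.

Relative expression uses the efficiency-corrected ratio
E_ref^CP(ref) / E_target^CP(target); efficiencies come from a cDNA
dilution series (1, 1:4, 1:8, 1:16, 1:32) via the standard-curve slope.
The segregation test checks observed phenotype counts against the
Mendelian 1:2:1 expectation for a single-locus trait.
"""

from bsakit import (
    DilutionSeries,
    QpcrMeasurement,
    SegregationCounts,
    knockdown_fraction,
    primer_efficiency,
    relative_expression,
    segregation_test,
)

# --- primer efficiency from a perfect-doubling dilution series
series = DilutionSeries(
    (1.0, 0.25, 0.125, 0.0625, 0.03125),
    ((18.0,), (20.0,), (21.0,), (22.0,), (23.0,)),
)
fit = primer_efficiency(series)
print(f"amplification efficiency E = {fit.efficiency:.3f} "
      f"(slope {fit.slope:.3f}, R^2 {fit.r_squared:.4f})")

# --- relative expression in wild type vs a strong RNAi line
e = fit.efficiency
wt = relative_expression(
    QpcrMeasurement("wt", "UBC", (19.8, 20.1, 20.0), e),
    QpcrMeasurement("wt", "FNS", (22.0, 21.9, 22.1), e),
)
rnai = relative_expression(
    QpcrMeasurement("line12", "UBC", (20.0, 20.1, 19.9), e),
    QpcrMeasurement("line12", "FNS", (26.6, 26.4, 26.5), e),
)
kd = knockdown_fraction(rnai, wt)
print(f"relative FNS expression: wild type {wt:.4f}, RNAi line {rnai:.4f}")
print(f"knockdown: {100 * kd:.1f}%  "
      "(>95% knockdown is the regime that phenocopies the null mutant)")

# --- does the F2 fit 1:2:1?
result = segregation_test(SegregationCounts((112, 235, 98), (1, 2, 1)))
print(f"\nF2 counts 112:235:98 vs 1:2:1 -> chi2 = {result.chi2:.3f}, "
      f"df = {result.df}, p = {result.p_value:.3f}")
print("the single-locus 1:2:1 model is not rejected" if result.p_value > 0.05
      else "segregation is distorted")
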