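"""Ruggedness, navigability, and epistasis diagnostics of a landscape.

The panel: local optima ratio (fraction of variants with no fitter
neighbor), roughness-slope ratio (deviation from the best additive fit),
neutrality index (fraction of near-neutral single-mutation steps), global
optimum accessibility (fraction of variants that can strictly climb to the
top), and the breakdown of epistatic squares into magnitude / sign /
reciprocal-sign classes.
"""

from eradev import (
    SyntheticSpec,
    analyze_landscape,
    generate_synthetic_landscape,
    scale_landscape,
)

for label, pairwise in (("smooth (no couplings)", 0.0), ("rugged (couplings)", 1.2)):
    spec = SyntheticSpec(
        n_positions=3, alphabet_size=6, pairwise_scale=pairwise,
        higher_order_scale=0.0, noise_sd=0.0, seed=5,
        link="linear" if pairwise == 0.0 else "exponential",
    )
    report = analyze_landscape(scale_landscape(generate_synthetic_landscape(spec)))
    e = report.epistasis
    print(f"\n{label}: {report.size} variants")
    print(f"  local optima ratio        {report.lor:.4f}  (1/{report.size} = single peak)")
    print(f"  roughness-slope ratio     {report.rs_ratio:.4f}  (0 = perfectly additive)")
    print(f"  neutrality index          {report.neutrality:.4f}")
    print(f"  global optimum access.    {report.goa:.4f}  (1 = every variant can climb up)")
    if e.no_epistasis:
        print("  epistasis: none — all squares additive")
    else:
        print(f"  epistasis over {e.n_epistatic}/{e.n_squares} non-additive squares: "
              f"magnitude {e.magnitude:.3f}, sign {e.sign:.3f}, "
              f"reciprocal sign {e.reciprocal_sign:.3f}")
print("\nsign and reciprocal-sign epistasis create the valleys that trap greedy search")
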