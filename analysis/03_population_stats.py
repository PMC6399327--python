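#!/usr/bin/env python
"""Population statistics over the per-track estimates.

Per condition: mean ± SEM of D and L, log-space Gaussian-mixture fits (AIC
over 1–3 components for D, 1–2 for L) with arithmetic component moments,
F-test-gated pairwise t-tests with significance stars, percent differences
against the epithelial baseline, and the Pearson correlation of mean D with
an external differentiation-score vector (more differentiated = lower
score; invasive conditions score lower).  Writes
results/analysis/popstats.json and the log-histogram figures.
"""

import json
from itertools import combinations
from pathlib import Path

import numpy as np

from tred import io
from tred.stats import (
    compare_groups,
    correlate,
    fit_log_mixture,
    percent_difference,
    significance_stars,
    summarize_group,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"

# external per-condition score vector (stand-in for a gene-expression-derived
# luminal differentiation score): higher = more differentiated/epithelial
SCORES = {"epithelial": 0.45, "emt_induced": -0.10, "mesenchymal": -0.60}


def main() -> None:
    df = io.read_estimates_csv(OUT / "estimates.csv")
    good = df[df["converged"]]
    out: dict = {"conditions": {}, "tests": [], "percent_differences": []}

    for name, g in good.groupby("condition"):
        d_vals, l_vals = g["D_um2_s"].to_numpy(), g["L_nm"].to_numpy()
        mix_d = fit_log_mixture(d_vals[d_vals > 0], 1, 3, seed=0)
        mix_l = fit_log_mixture(l_vals[l_vals > 0], 1, 2, seed=0)
        out["conditions"][name] = {
            "n": int(len(g)),
            "D": vars(summarize_group(d_vals)),
            "L_nm": vars(summarize_group(l_vals)),
            "mixture_D": {
                "K": mix_d.K,
                "labels": mix_d.component_labels,
                "weights": mix_d.weights.round(3).tolist(),
                "arithmetic_means": mix_d.arithmetic_means.tolist(),
                "arithmetic_sds": mix_d.arithmetic_sds.tolist(),
            },
            "mixture_L": {
                "K": mix_l.K,
                "labels": mix_l.component_labels,
                "weights": mix_l.weights.round(3).tolist(),
                "arithmetic_means": mix_l.arithmetic_means.tolist(),
            },
        }
        print(f"{name}: mixture K(D)={mix_d.K}, K(L)={mix_l.K}, "
              f"D weights {mix_d.weights.round(2).tolist()}")

    names = sorted(out["conditions"])
    for a, b in combinations(names, 2):
        for col in ("D_um2_s", "L_nm"):
            res = compare_groups(
                good.loc[good["condition"] == a, col].to_numpy(),
                good.loc[good["condition"] == b, col].to_numpy(),
            )
            stars = significance_stars(res.p_value)
            out["tests"].append(
                {"a": a, "b": b, "quantity": col, "t": res.t_stat, "df": res.df,
                 "p": res.p_value, "variant": res.variant, "stars": stars}
            )
            print(f"{a} vs {b} [{col}]: t={res.t_stat:.2f} ({res.variant}), "
                  f"p={res.p_value:.2e} {stars}")

    ref = "epithelial"
    ref_D = out["conditions"][ref]["D"]["mean"]
    ref_L = out["conditions"][ref]["L_nm"]["mean"]
    for name in names:
        if name == ref:
            continue
        dd = percent_difference(out["conditions"][name]["D"]["mean"], ref_D, rounded=True)
        dl = percent_difference(out["conditions"][name]["L_nm"]["mean"], ref_L, rounded=True)
        out["percent_differences"].append({"condition": name, "D_pct": dd, "L_pct": dl})
        print(f"{name} vs {ref}: D {dd:+.0f}%, L {dl:+.0f}%")

    r = correlate(
        [out["conditions"][n]["D"]["mean"] for n in names],
        [SCORES[n] for n in names],
    )
    out["correlation_mean_D_vs_score"] = r
    print(f"Pearson r (mean D vs differentiation score) = {r:.2f}")

    (OUT / "popstats.json").write_text(json.dumps(out, indent=2, sort_keys=True))

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    for name, g in good.groupby("condition"):
        vals = g.loc[g["D_um2_s"] > 0, "D_um2_s"].to_numpy()
        mix = fit_log_mixture(vals, 1, 3, seed=0)
        logs = np.log10(vals)
        fig, ax = plt.subplots(figsize=(4, 3))
        counts, bins, _ = ax.hist(logs, bins=40, alpha=0.5, color="gray")
        bw = bins[1] - bins[0]
        grid = np.linspace(bins[0], bins[-1], 300)
        for w, mu, sd, lab in zip(mix.weights, mix.means_log10, mix.sds_log10,
                                  mix.component_labels):
            ax.plot(grid, w * len(vals) * bw * norm.pdf(grid, mu, sd), label=lab)
        ax.set_xlabel("log10 D (µm²/s)")
        ax.set_title(name)
        ax.legend(fontsize=7)
        fig.savefig(OUT / f"hist_logD_{name}.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
    print(f"report -> {OUT / 'popstats.json'}")


if __name__ == "__main__":
    main()
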