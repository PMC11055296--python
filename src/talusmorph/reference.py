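"""Recompute the published reference cohort's statistics from its printed
(n, mean, SD) summaries.

The raw cohort behind the reference summaries is not deposited anywhere, so
the check works entirely at the summary level: the region ANOVA, the two
fitted-radius t tests and the count-weighted pooled mean are recomputed from
the printed summaries and compared against the printed statistics. Residual
discrepancy is attributable to the 2-decimal rounding of the printed values.
"""

from __future__ import annotations

import json
from importlib import resources

from .stats import (
    GroupSummary,
    lsd_pairwise,
    oneway_anova_from_summaries,
    pooled_t_from_summaries,
    weighted_pool,
)

__all__ = ["load_reference_summaries", "recompute_reference_statistics"]


def load_reference_summaries() -> dict:
    """The bundled reference-cohort summary document."""
    with resources.files("talusmorph.data").joinpath(
        "reference_summaries.json"
    ).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def _summary(entry: dict, label: str) -> GroupSummary:
    return GroupSummary(n=int(entry["n"]), mean=float(entry["mean"]),
                        sd=float(entry["sd"]), label=label)


def recompute_reference_statistics(reference: dict | None = None) -> dict:
    """Recompute every summary-level statistic and pair it with its printed value.

    Returns a dict keyed by statistic name, each entry carrying the observed
    (recomputed) value, the printed value, and their relative deviation.
    """
    ref = reference if reference is not None else load_reference_summaries()
    printed = ref["printed_statistics"]

    regions = [_summary(v, k) for k, v in ref["regions"].items()]
    anova = oneway_anova_from_summaries(regions)

    fitted = ref["fitted_radius"]
    t_sex = pooled_t_from_summaries(
        _summary(fitted["male"], "male"), _summary(fitted["female"], "female")
    )
    t_side = pooled_t_from_summaries(
        _summary(fitted["right"], "right"), _summary(fitted["left"], "left")
    )
    pooled_sex = weighted_pool(
        [_summary(fitted["male"], "male"), _summary(fitted["female"], "female")]
    )
    pooled_side = weighted_pool(
        [_summary(fitted["right"], "right"), _summary(fitted["left"], "left")]
    )

    lsd = {r.label: r for r in lsd_pairwise(regions)}

    def entry(observed, printed_value):
        rel = abs(observed - printed_value) / abs(printed_value) if printed_value else None
        return {"observed": float(observed), "printed": float(printed_value),
                "relative_deviation": rel}

    out = {
        "anova_regions_F": entry(anova.value, printed["anova_regions_F"]),
        "fitted_t_male_vs_female": entry(t_sex.value, printed["fitted_t_male_vs_female"]),
        "fitted_t_right_vs_left": entry(t_side.value, printed["fitted_t_right_vs_left"]),
        "pooled_fitted_mean_by_sex": entry(pooled_sex.mean, printed["pooled_fitted_mean"]),
        "pooled_fitted_mean_by_side": entry(pooled_side.mean, printed["pooled_fitted_mean"]),
        "pooled_fitted_sd_by_sex": entry(pooled_sex.sd, printed["pooled_fitted_sd"]),
    }
    out["anova_df"] = list(anova.df)
    out["lsd_adjacent_p"] = {
        label: lsd[label].p_two_sided
        for label in ("PL vs PM", "PL vs MP", "AL vs PL", "AL vs MA", "AM vs AL")
        if label in lsd
    }
    return out
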