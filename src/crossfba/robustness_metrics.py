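"""Community robustness metrics and variance statistics.

Three per-mutant metrics compare a perturbed community's final biomasses
``(E, S)`` with the unperturbed pair ``(Eu, Su)`` of the same growth
condition:

* **ECD** (Euclidean community distance): percent deviation of the final
  biomass vector, ``100 * ||(E - Eu, S - Su)|| / ||(Eu, Su)||``.
* **%E** (normalized composition): the fraction of E in the community,
  normalized to the unperturbed fraction.
* **BM** (normalized biomass): total community biomass over the unperturbed
  total.

Robustness of a growth condition is then summarized by the standard
deviation of each metric over mutants, equality of variances between
conditions is tested with a mean-centered Levene test (one-way ANOVA on
absolute deviations from group means), substantive knockouts are counted at
a 1% departure from the unperturbed value, and per-mutant effects are
correlated across conditions (Pearson R^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    ExtinctCommunityError,
    InsufficientDataError,
    UndefinedReferenceError,
)

#: smallest p-value reported in summary tables (printing floor, not a test change)
P_FLOOR = 2.2e-16

METRICS = ("ECD", "pctE_norm", "BM_norm")


def ecd(E: float, S: float, Eu: float, Su: float) -> float:
    """Euclidean community distance, in percent of the unperturbed magnitude.

    Zero exactly when the perturbed community reaches the unperturbed
    biomasses; invariant to rescaling all four biomasses by a common factor.
    """
    if Eu == 0 and Su == 0:
        raise UndefinedReferenceError("unperturbed biomasses are both zero")
    return 100.0 * float(
        np.hypot(E - Eu, S - Su) / np.hypot(Eu, Su)
    )


def normalized_percent_e(E: float, S: float, Eu: float, Su: float) -> float:
    """Fraction of E in the community, normalized to the unperturbed fraction."""
    if Eu <= 0:
        raise UndefinedReferenceError("unperturbed E biomass must be positive")
    if Eu + Su <= 0:
        raise UndefinedReferenceError("unperturbed community is empty")
    if E + S <= 0:
        raise ExtinctCommunityError("perturbed community is extinct (E + S = 0)")
    return (E / (E + S)) / (Eu / (Eu + Su))


def normalized_bm(E: float, S: float, Eu: float, Su: float) -> float:
    """Total community biomass normalized to the unperturbed total."""
    if Eu + Su <= 0:
        raise UndefinedReferenceError("unperturbed community is empty")
    return (E + S) / (Eu + Su)


@dataclass(frozen=True)
class LeveneResult:
    W: float
    df1: int
    df2: int
    p: float


def levene_mean_centered(groups) -> LeveneResult:
    """Mean-centered Levene test for equality of variances across k >= 2 groups.

    Computes a one-way ANOVA on the absolute deviations from each group's
    mean, Z_ij = |x_ij - mean_i|:

        W = (N - k)/(k - 1) * sum_i n_i (Zbar_i - Zbar)^2
                              / sum_ij (Z_ij - Zbar_i)^2

    and the p-value from the upper tail of F(k-1, N-k). The mean-centered
    variant (not the median-centered Brown-Forsythe) is used throughout.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two values")
    k = len(groups)
    n = np.array([len(g) for g in groups])
    N = int(n.sum())
    Z = [np.abs(g - g.mean()) for g in groups]
    zbar_i = np.array([z.mean() for z in Z])
    zbar = sum(z.sum() for z in Z) / N
    between = float(np.sum(n * (zbar_i - zbar) ** 2))
    within = float(sum(((z - zb) ** 2).sum() for z, zb in zip(Z, zbar_i)))
    if within == 0:
        # Every group's absolute deviations are internally identical. If the
        # per-group spreads are equal and nonzero there is exactly no
        # evidence against equal variances (W = 0); otherwise W is 0/0 or
        # infinite and the test is undefined.
        if between == 0 and zbar > 0:
            return LeveneResult(W=0.0, df1=k - 1, df2=N - k, p=1.0)
        raise DegenerateVarianceError(
            "within-group absolute deviations have zero sum of squares"
        )
    W = (N - k) / (k - 1) * between / within
    p = float(stats.f.sf(W, k - 1, N - k))
    return LeveneResult(W=float(W), df1=k - 1, df2=N - k, p=p)


def count_substantive(values, threshold: float = 0.01) -> int:
    """Number of normalized metric values departing from 1 by >= threshold.

    The boundary is inclusive (a value at exactly 1 + threshold counts); a
    tiny tolerance absorbs float representation of the threshold itself.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        return 0
    return int(np.sum(np.abs(values - 1.0) >= threshold - 1e-12))


def effect_r2(x, y) -> float:
    """Squared Pearson correlation between per-mutant effects in two conditions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# screen-level summaries
# ---------------------------------------------------------------------------

@dataclass
class ReportTables:
    """Tabular summary of a two-condition knockout screen.

    ``sigma``: standard deviation (n-1 denominator) of each metric per
    condition, with and without reactions essential in any context.
    ``levene``: cooperation-vs-competition variance-equality tests.
    ``substantive_counts``: mutants moving %E or BM by >= the substantive
    threshold. ``r2``: cross-condition Pearson R^2 of per-mutant effects.
    """

    sigma: pd.DataFrame
    levene: pd.DataFrame
    substantive_counts: pd.DataFrame
    r2: pd.DataFrame

    def write(self, directory, provenance: dict | None = None) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in [
            ("sigma", self.sigma),
            ("levene", self.levene),
            ("substantive_counts", self.substantive_counts),
            ("r2", self.r2),
        ]:
            with open(directory / f"report_{name}.tsv", "w") as fh:
                for key, value in (provenance or {}).items():
                    fh.write(f"# {key}: {value}\n")
                df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reaction_id": [r.reaction_id for r in records],
            "condition": [r.condition for r in records],
            "ECD": [r.ECD for r in records],
            "pctE_norm": [r.pctE_norm for r in records],
            "BM_norm": [r.BM_norm for r in records],
            "essential_any": [
                bool(r.essential_monoculture)
                or bool(r.essential_cooperation)
                or bool(r.essential_competition)
                for r in records
            ],
        }
    )


def summarize_screen(
    result,
    config,
    include_essential_in_r2: bool = False,
) -> ReportTables:
    """Build the report tables from a finished two-condition screen.

    Mutants essential in *any* context (monoculture, cooperation or
    competition) are excluded from the "non_essential" rows, mirroring how
    lethal perturbations are set aside when quantifying the impact of
    non-lethal ones; "all" rows include everything. Mutants whose community
    went extinct (undefined composition) are excluded from %E statistics.
    p-values in the Levene table are floored at ``P_FLOOR`` for reporting.
    """
    df = _records_frame(result.records)
    conditions = sorted(df["condition"].unique())
    if not {"cooperation", "competition"} <= set(conditions):
        raise ValueError(
            "summaries need both cooperation and competition; "
            f"screen has {conditions}"
        )
    pair = ["cooperation", "competition"]
    df = df[df["condition"].isin(pair)]

    non_essential = df[~df["essential_any"]]
    n_non_essential = non_essential["reaction_id"].nunique()
    if n_non_essential < 2:
        raise InsufficientDataError(
            f"only {n_non_essential} non-essential mutants; need at least 2"
        )

    sigma_rows = []
    for metric in METRICS:
        for condition in pair:
            for mode, sub in (("non_essential", non_essential), ("all", df)):
                vals = sub.loc[sub["condition"] == condition, metric].dropna()
                sigma_rows.append(
                    {
                        "metric": metric,
                        "condition": condition,
                        "inclusion": mode,
                        "sigma": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                        "n": int(len(vals)),
                    }
                )
    sigma = pd.DataFrame(sigma_rows)

    levene_rows = []
    for metric in METRICS:
        for mode, sub in (("non_essential", non_essential), ("all", df)):
            groups = [
                sub.loc[sub["condition"] == c, metric].dropna().to_numpy()
                for c in pair
            ]
            row = {"metric": metric, "inclusion": mode}
            try:
                res = levene_mean_centered(groups)
                row.update(
                    W=res.W, df1=res.df1, df2=res.df2, p=max(res.p, P_FLOOR), note=""
                )
            except (DegenerateVarianceError, ValueError) as exc:
                row.update(W=np.nan, df1=np.nan, df2=np.nan, p=np.nan, note=str(exc))
            levene_rows.append(row)
    levene = pd.DataFrame(levene_rows)

    count_rows = []
    for metric in ("pctE_norm", "BM_norm"):
        for condition in pair:
            vals = non_essential.loc[
                non_essential["condition"] == condition, metric
            ].dropna()
            count_rows.append(
                {
                    "metric": metric,
                    "condition": condition,
                    "substantive": count_substantive(
                        vals, getattr(config, "substantive_threshold", 0.01)
                    ),
                    "n": int(len(vals)),
                }
            )
    counts = pd.DataFrame(count_rows)

    r2_rows = []
    base = df if include_essential_in_r2 else non_essential
    for metric in ("pctE_norm", "BM_norm"):
        wide = base.pivot_table(
            index="reaction_id", columns="condition", values=metric
        ).dropna()
        row = {"metric": metric, "n": int(len(wide))}
        try:
            row["r2"] = effect_r2(wide["cooperation"], wide["competition"])
        except ValueError as exc:
            row["r2"] = np.nan
            row["note"] = str(exc)
        r2_rows.append(row)
    r2 = pd.DataFrame(r2_rows)

    return ReportTables(sigma=sigma, levene=levene, substantive_counts=counts, r2=r2)
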