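"""Plasticity traits: replicate averaging, treatment contrasts, summaries.

A reciprocal two-generation light experiment yields six treatments:
parental plants in high (H) or low (L) light, and offspring grown in
high/low light from a high- or low-light maternal environment (HH, HL,
LH, LL — first letter maternal, second offspring).  Phenotypic
plasticity of a RIL is the week-by-week difference of its
replicate-averaged leaf-number trajectory between two treatments:

* within-generational plasticity: pWPP = L - H (parents),
  oWPP_H = HL - HH and oWPP_L = LL - LH (offspring);
* transgenerational plasticity: TPP_H = HH - H, TPP_L = LL - L;
* maternal plasticity: MPP_H = HH - LH, MPP_L = LL - HL.

All contrasts are computed per RIL over the shared time grid, so a
plasticity trait is itself a time-course trait and can be mapped with
functional mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .growth import TimeGrid, fit_logistic

__all__ = [
    "TREATMENTS",
    "CONTRASTS",
    "TrajectoryPanel",
    "PlasticityTrait",
    "average_replicates",
    "compute_plasticity",
    "asymptotic_summary",
    "test_contrasts",
]

TREATMENTS = ("H", "L", "HH", "HL", "LH", "LL")

#: contrast name -> (minuend treatment, subtrahend treatment)
CONTRASTS: dict[str, tuple[str, str]] = {
    "pWPP": ("L", "H"),
    "oWPP_H": ("HL", "HH"),
    "oWPP_L": ("LL", "LH"),
    "TPP_H": ("HH", "H"),
    "TPP_L": ("LL", "L"),
    "MPP_H": ("HH", "LH"),
    "MPP_L": ("LL", "HL"),
}


@dataclass
class TrajectoryPanel:
    """Replicate-averaged RIL x week leaf numbers for one treatment."""

    treatment: str
    ril_ids: list
    values: np.ndarray  # (n_ril, T)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ril_ids):
            raise ValueError("values must be (n_ril, T) matching ril_ids")
        if len(set(self.ril_ids)) != len(self.ril_ids):
            raise ValueError("duplicated RIL ids in panel")

    @property
    def n_ril(self) -> int:
        return len(self.ril_ids)

    def subset(self, ril_ids) -> "TrajectoryPanel":
        index = {r: i for i, r in enumerate(self.ril_ids)}
        rows = [index[r] for r in ril_ids]
        return TrajectoryPanel(self.treatment, list(ril_ids), self.values[rows])


@dataclass
class PlasticityTrait:
    """Per-RIL time-course difference z_i = x_i - y_i for one contrast.

    The minuend (x) and subtrahend (y) panels are kept alongside the
    difference because the mapping model initialises its component growth
    curves from them.
    """

    name: str
    minuend: str
    subtrahend: str
    ril_ids: list
    values: np.ndarray  # (n_ril, T), z_i rows
    x_values: np.ndarray = field(repr=False, default=None)
    y_values: np.ndarray = field(repr=False, default=None)

    @property
    def n_ril(self) -> int:
        return len(self.ril_ids)


_REQUIRED_COLS = ("ril_id", "treatment", "replicate", "week", "leaf_number")


def average_replicates(raw: pd.DataFrame, grid: TimeGrid) -> dict[str, TrajectoryPanel]:
    """Average leaf numbers over replicates, one panel per treatment.

    ``raw`` is the long table with columns ril_id, treatment, replicate,
    week, leaf_number.  Missing replicate values are ignored in the mean;
    a RIL is dropped from a treatment panel if any week has zero observed
    replicates (the drop is recorded nowhere here — callers log it).
    """
    missing = [c for c in _REQUIRED_COLS if c not in raw.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    weeks = np.asarray(grid.values)
    week_set = {int(w) for w in weeks}
    bad_weeks = set(raw["week"].unique()) - week_set
    if bad_weeks:
        raise ValueError(f"week values {sorted(bad_weeks)} outside the time grid")
    bad_treat = set(raw["treatment"].unique()) - set(TREATMENTS)
    if bad_treat:
        raise ValueError(f"unknown treatment labels {sorted(bad_treat)}")

    panels: dict[str, TrajectoryPanel] = {}
    means = (
        raw.groupby(["treatment", "ril_id", "week"], sort=True)["leaf_number"]
        .mean()
        .reset_index()
    )
    for treatment, sub in means.groupby("treatment", sort=True):
        wide = sub.pivot(index="ril_id", columns="week", values="leaf_number")
        wide = wide.reindex(columns=sorted(week_set))
        complete = wide.dropna(axis=0, how="any")
        panels[treatment] = TrajectoryPanel(
            treatment, list(complete.index), complete.to_numpy(dtype=float)
        )
    return panels


def compute_plasticity(name: str, panels: dict[str, TrajectoryPanel]) -> PlasticityTrait:
    """Build the plasticity trait for one named contrast.

    Rows are restricted to RILs present in both source panels; each row is
    the elementwise difference minuend - subtrahend.
    """
    if name not in CONTRASTS:
        raise ValueError(f"unknown contrast {name!r}; valid: {sorted(CONTRASTS)}")
    minu, subt = CONTRASTS[name]
    for lab in (minu, subt):
        if lab not in panels:
            raise ValueError(f"contrast {name} needs treatment panel {lab!r}")
    px, py = panels[minu], panels[subt]
    shared = [r for r in px.ril_ids if r in set(py.ril_ids)]
    if len(shared) < 2:
        raise ValueError(f"contrast {name}: fewer than 2 RILs shared between panels")
    x = px.subset(shared).values
    y = py.subset(shared).values
    return PlasticityTrait(name, minu, subt, shared, x - y, x_values=x, y_values=y)


def _ril_asymptotes(panel: TrajectoryPanel, grid: TimeGrid) -> tuple[np.ndarray, int]:
    """Fitted asymptote a per RIL; week-final value when the fit fails."""
    out = np.empty(panel.n_ril)
    n_fallback = 0
    for i in range(panel.n_ril):
        try:
            fit = fit_logistic(panel.values[i], grid)
        except (ValueError, RuntimeError):
            fit = None
        if fit is not None and fit.success:
            out[i] = fit.params.a
        else:
            out[i] = panel.values[i, -1]
            n_fallback += 1
    return out, n_fallback


def asymptotic_summary(panels: dict[str, TrajectoryPanel], grid: TimeGrid) -> pd.DataFrame:
    """Across-RIL mean +/- SE of the asymptotic leaf number per treatment.

    The per-RIL asymptote is the fitted logistic ``a`` (falling back to
    the final-week value when the fit does not converge); the SE
    describes variation across RILs.
    """
    rows = []
    for label, panel in panels.items():
        if panel.n_ril == 0:
            raise ValueError(f"treatment {label!r} has no RILs")
        asym, n_fb = _ril_asymptotes(panel, grid)
        n = asym.size
        se = float(np.std(asym, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            {
                "treatment": label,
                "n_ril": n,
                "mean_asymptote": float(np.mean(asym)),
                "se": se,
                "n_fallback": n_fb,
            }
        )
    return pd.DataFrame(rows)


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(np.mean(a), np.mean(b)) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _compact_letters(names: list[str], sig: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a significance matrix.

    ``sig[i, j]`` is True when groups i and j differ significantly; groups
    sharing a letter are not significantly different.
    """
    k = len(names)
    letter_sets: list[set[int]] = [set(range(k))] if k else []
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            for s in [s for s in letter_sets if i in s and j in s]:
                letter_sets.remove(s)
                si, sj = s - {j}, s - {i}
                for cand in (si, sj):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets.sort(key=lambda s: (min(s), -len(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {n: "" for n in names}
    for li, s in enumerate(letter_sets):
        for idx in sorted(s):
            out[names[idx]] += alphabet[li % len(alphabet)]
    return out


def test_contrasts(
    traits: dict[str, PlasticityTrait],
    grid: TimeGrid,
    comparisons: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Significance summary of asymptotic plasticity across contrasts.

    Per contrast a per-RIL scalar is built as the difference of fitted
    asymptotes between the minuend and subtrahend trajectories (final-week
    difference when a fit fails).  A two-sided one-sample t-test checks
    mean plasticity != 0; Welch t-tests compare the requested contrast
    pairs; Benjamini-Hochberg adjustment is applied across the whole
    family and compact letters summarise the adjusted pairwise matrix.
    """
    if comparisons is None:
        pairs = [
            (a, b)
            for a, b in [("oWPP_L", "oWPP_H"), ("TPP_H", "TPP_L"), ("MPP_H", "MPP_L")]
            if a in traits and b in traits
        ]
    else:
        pairs = list(comparisons)

    per_ril: dict[str, np.ndarray] = {}
    for name, trait in traits.items():
        if trait.n_ril < 2:
            raise ValueError(f"contrast {name}: need >= 2 RILs")
        xs, _ = _ril_asymptotes(
            TrajectoryPanel(trait.minuend, trait.ril_ids, trait.x_values), grid
        )
        ys, _ = _ril_asymptotes(
            TrajectoryPanel(trait.subtrahend, trait.ril_ids, trait.y_values), grid
        )
        per_ril[name] = xs - ys

    records = []
    pvals = []
    for name, vals in per_ril.items():
        if np.allclose(np.var(vals), 0.0):
            p = 1.0 if np.isclose(np.mean(vals), 0.0) else 0.0
        else:
            p = float(stats.ttest_1samp(vals, 0.0).pvalue)
        records.append(
            {
                "test": "one_sample",
                "contrast": name,
                "vs": "0",
                "mean": float(np.mean(vals)),
                "se": float(np.std(vals, ddof=1) / np.sqrt(vals.size)),
                "p_raw": p,
            }
        )
        pvals.append(p)
    for a, b in pairs:
        p = _welch(per_ril[a], per_ril[b])
        records.append(
            {
                "test": "pairwise",
                "contrast": a,
                "vs": b,
                "mean": float(np.mean(per_ril[a]) - np.mean(per_ril[b])),
                "se": np.nan,
                "p_raw": p,
            }
        )
        pvals.append(p)

    adj = stats.false_discovery_control(np.asarray(pvals), method="bh")
    table = pd.DataFrame(records)
    table["p_adj"] = adj

    # compact letters from the adjusted pairwise matrix over contrasts
    names = list(per_ril)
    sig = np.zeros((len(names), len(names)), dtype=bool)
    for row in table[table["test"] == "pairwise"].itertuples():
        i, j = names.index(row.contrast), names.index(row.vs)
        sig[i, j] = sig[j, i] = row.p_adj < alpha
    letters = _compact_letters(names, sig)
    table["letter"] = [
        letters.get(r.contrast, "") if r.test == "one_sample" else ""
        for r in table.itertuples()
    ]
    return table
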