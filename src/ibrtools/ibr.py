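"""Integrated Biomarker Response, version 2 (IBRv2).

Per biomarker, individual responses are log-transformed (by default as the
log ratio to the reference-group mean, Y_i = ln(X_i / mean(X_ref))), then
standardised against the grand mean and SD of the whole data set,
Z_i = (Y_i - mean(Y)) / sd(Y).  The deviation index of exposure group g is

    A[g, b] = mean(Z in g) - mean(Z in reference group),

positive for stimulation relative to the reference and negative for
inhibition.  The per-group IBRv2 score is the sum of |A| across
biomarkers.  Unlike the original star-plot-area index, IBRv2 does not
depend on the ordering of biomarkers, and it is invariant to rescaling
any biomarker by a positive constant (the log turns scale factors into
shifts, which standardisation removes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IBRConfig",
    "IBRResult",
    "ConstantBiomarkerError",
    "NonPositiveValueError",
    "standardize_biomarker",
    "deviation_indices",
    "ibr_score",
    "compute_ibr",
    "radar_data",
]


class ConstantBiomarkerError(ValueError):
    """A biomarker has zero overall SD and cannot be standardised."""


class NonPositiveValueError(ValueError):
    """A non-positive value reached the log step with zero offset."""


@dataclass(frozen=True)
class IBRConfig:
    """Configuration of the IBRv2 computation.

    log_mode "log_ratio_to_reference_mean" is the standard IBRv2
    convention; "plain_log" simply logs the raw values.  Both produce
    identical deviation indices because the reference-mean factor is a
    per-biomarker constant that cancels in standardisation, as does the
    choice of log base.
    """

    reference_group: str = "A1"
    log_mode: str = "log_ratio_to_reference_mean"  # | "plain_log"
    log_base: str = "natural"  # | "base10"
    zero_offset: float = 0.0  # added before the log; 0 => error on non-positive


@dataclass
class IBRResult:
    """Deviation-index matrix and per-group IBRv2 scores."""

    biomarkers: list[str]
    groups: list[str]
    A: pd.DataFrame  # groups x biomarkers, signed
    scores: pd.Series  # per group, sum of |A| over non-missing biomarkers
    n_biomarkers_used: pd.Series
    config: IBRConfig = field(default_factory=IBRConfig)

    @property
    def abs_A(self) -> pd.DataFrame:
        return self.A.abs()


def _log(values: np.ndarray, config: IBRConfig, label: str) -> np.ndarray:
    v = values + config.zero_offset
    if np.any(v <= 0):
        bad = np.flatnonzero(v <= 0)
        raise NonPositiveValueError(
            f"{label}: non-positive value at row(s) {bad.tolist()} with zero_offset="
            f"{config.zero_offset}; the log step is undefined"
        )
    out = np.log(v)
    if config.log_base == "base10":
        out = out / np.log(10.0)
    return out


def standardize_biomarker(
    values: np.ndarray,
    groups: np.ndarray,
    config: IBRConfig,
    biomarker: str = "?",
) -> np.ndarray:
    """Log-transform one biomarker's values and Z-score them over all animals.

    The SD is the sample SD (ddof=1) of the pooled data set; the mean and
    SD pool every group, including the reference.
    """
    values = np.asarray(values, dtype=float)
    if config.log_mode == "log_ratio_to_reference_mean":
        ref = values[np.asarray(groups) == config.reference_group]
        ref = ref[np.isfinite(ref)]
        if ref.size == 0:
            raise ValueError(f"{biomarker}: reference group {config.reference_group!r} empty")
        y = _log(values / np.nanmean(ref), config, biomarker)
    elif config.log_mode == "plain_log":
        y = _log(values, config, biomarker)
    else:
        raise ValueError(f"unknown log_mode {config.log_mode!r}")
    mask = np.isfinite(y)
    sd = np.std(y[mask], ddof=1)
    if not sd > 0:
        raise ConstantBiomarkerError(f"{biomarker}: overall SD is zero; cannot standardise")
    z = np.full_like(y, np.nan)
    z[mask] = (y[mask] - np.mean(y[mask])) / sd
    return z


def deviation_indices(
    z: np.ndarray, groups: np.ndarray, reference_group: str
) -> pd.Series:
    """Per-group deviation index: mean Z of the group minus mean Z of the reference.

    The reference row is exactly 0 by construction.  A group with no finite
    Z yields a missing (NaN) index.
    """
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} absent from data")
    zref = z[groups == reference_group]
    zref = zref[np.isfinite(zref)]
    if zref.size == 0:
        raise ValueError(f"reference group {reference_group!r} has no finite values")
    ref_mean = float(np.mean(zref))
    out = {}
    for g in labels:
        zg = z[groups == g]
        zg = zg[np.isfinite(zg)]
        out[g] = float(np.mean(zg)) - ref_mean if zg.size else np.nan
    out[reference_group] = 0.0
    return pd.Series(out)


def ibr_score(deviations: "pd.Series | np.ndarray") -> tuple[float, int]:
    """IBRv2 score: sum of |A| over non-missing deviation indices.

    Returns (score, number of biomarkers included); an all-missing row
    yields (NaN, 0).
    """
    a = np.asarray(deviations, dtype=float)
    mask = np.isfinite(a)
    if not mask.any():
        return float("nan"), 0
    return float(np.sum(np.abs(a[mask]))), int(mask.sum())


def compute_ibr(
    table: pd.DataFrame,
    biomarkers: list[str] | None = None,
    config: IBRConfig | None = None,
    group_col: str = "group",
) -> IBRResult:
    """Compute the full IBRv2 result for a tidy biomarker table."""
    config = config or IBRConfig()
    if biomarkers is None:
        biomarkers = [
            c for c in table.columns if c not in ("animal_id", group_col)
        ]
    groups_arr = table[group_col].astype(str).to_numpy()
    labels = list(dict.fromkeys(groups_arr))
    if config.reference_group not in labels:
        raise ValueError(f"reference group {config.reference_group!r} not in table")
    cols = {}
    for b in biomarkers:
        z = standardize_biomarker(table[b].to_numpy(dtype=float), groups_arr, config, b)
        cols[b] = deviation_indices(z, groups_arr, config.reference_group)
    A = pd.DataFrame(cols).reindex(labels)
    scores = {}
    used = {}
    for g in labels:
        s, n = ibr_score(A.loc[g])
        scores[g], used[g] = s, n
    return IBRResult(
        biomarkers=list(biomarkers),
        groups=labels,
        A=A,
        scores=pd.Series(scores),
        n_biomarkers_used=pd.Series(used),
        config=config,
    )


def radar_data(result: IBRResult) -> dict[str, list[tuple[str, float]]]:
    """Per-group polygon of signed deviation indices for radar plotting.

    Biomarker order is fixed and identical across groups; the reference
    group is the all-zero baseline ring.
    """
    return {
        g: [(b, float(result.A.loc[g, b])) for b in result.biomarkers]
        for g in result.groups
    }


def plot_radar(result: IBRResult, path=None):
    """Draw one radar (spider) plot per exposure group versus the zero baseline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    polys = radar_data(result)
    groups = [g for g in result.groups if g != result.config.reference_group]
    n = len(result.biomarkers)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, axes = plt.subplots(
        1, max(len(groups), 1), subplot_kw={"projection": "polar"},
        figsize=(4 * max(len(groups), 1), 4),
    )
    axes = np.atleast_1d(axes)
    for ax, g in zip(axes, groups):
        vals = np.array([v for _, v in polys[g]])
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=g)
        ax.plot(np.r_[angles, angles[0]], np.zeros(n + 1), "k--", lw=0.8, label="baseline")
        ax.set_xticks(angles)
        ax.set_xticklabels(result.biomarkers, fontsize=7)
        ax.set_title(f"{g}  (IBRv2 = {result.scores[g]:.2f})", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
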