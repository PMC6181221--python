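"""Ks-distribution peak detection and molecular-clock dating.

A WGD leaves a peak in the distribution of pairwise synonymous divergences of
retained duplicates; an interspecies divergence leaves a peak in the ortholog
Ks distribution.  Peaks are located by fitting Gaussian mixtures to ln(Ks)
with the component count chosen by BIC (kernel-density fallback when the fit
degenerates), and a modal Ks converts to absolute time by

    T = Ks / (2 r)

where r is the synonymous substitution rate per site per year.  The default
r = 6.68e-9 reproduces the conversion modal Ks 0.035 -> 2.62 MYA and sits in
the usual dicot range; it is user-overridable everywhere and echoed in every
result.  The same clock dates LTR retrotransposon insertions from the K2P
divergence of their 5' and 3' terminal repeats (identical at insertion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from .kaks import NucDistance, k2p

__all__ = [
    "DEFAULT_RATE",
    "KsDistribution",
    "Peak",
    "WgdEvent",
    "LtrElement",
    "build_distribution",
    "detect_peaks",
    "ks_to_time",
    "fit_wgd_events",
    "date_ltr",
    "plot_distribution",
]

#: substitutions per synonymous site per year
DEFAULT_RATE = 6.68e-9

DEFAULT_KS_CAP = 3.0


@dataclass
class KsDistribution:
    values: np.ndarray
    weights: np.ndarray
    source: str = "paralog"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights differ in shape")
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("Ks values must be finite and >= 0")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be > 0")

    def __len__(self) -> int:
        return len(self.values)


class Peak(NamedTuple):
    modal_ks: float
    mass: float
    method: str  # 'gmm' or 'kde'


@dataclass
class WgdEvent:
    label: str
    modal_ks: float
    mass: float
    rate_r: float
    time_mya: float


@dataclass
class LtrElement:
    element_id: str
    ltr5: str
    ltr3: str
    distance: NucDistance
    rate_r: float
    insertion_time_mya: float | None  # None when the distance is saturated


def build_distribution(
    ks_table: pd.DataFrame,
    weighting: str = "pair",
    cap: float = DEFAULT_KS_CAP,
    family_of: dict[str, str] | None = None,
    source: str = "paralog",
) -> KsDistribution:
    """Filter a Ks table into a weighted distribution.

    Rows whose status is not 'ok' (saturated, low-coverage) and values above
    `cap` are excluded.  Under family-average weighting each gene family
    contributes one unit of weight split equally over its pairs, so large
    families do not dominate the distribution; `family_of` maps gene_id ->
    family_id.
    """
    if weighting not in ("pair", "family-average"):
        raise ValueError("weighting must be 'pair' or 'family-average'")
    ok = ks_table[
        (ks_table["status"] == "ok")
        & np.isfinite(ks_table["Ks"])
        & (ks_table["Ks"] <= cap)
    ].copy()
    if ok.empty:
        raise ValueError("no usable Ks values after filtering")
    if weighting == "pair":
        weights = np.ones(len(ok))
    else:
        if family_of is None:
            raise ValueError("family-average weighting requires family_of")
        fams = [
            family_of.get(a) or family_of.get(b)
            for a, b in zip(ok["gene_a"], ok["gene_b"])
        ]
        ok["_fam"] = [f if f is not None else f"pair:{a}:{b}" for f, a, b in zip(fams, ok["gene_a"], ok["gene_b"])]
        sizes = ok.groupby("_fam")["_fam"].transform("size")
        weights = (1.0 / sizes).to_numpy()
    return KsDistribution(ok["Ks"].to_numpy(), weights, source)


def detect_peaks(
    dist: KsDistribution, max_components: int = 3, seed: int = 0
) -> list[Peak]:
    """Locate peaks of a Ks distribution.

    A Gaussian mixture is fitted to ln(Ks) for 1..max_components components
    and the component count chosen by BIC; modal Ks = exp(component mean).
    Non-uniform weights are honoured by weighted resampling before the fit.
    On a degenerate fit the method falls back to local maxima of a Gaussian
    kernel density (Silverman bandwidth), reported with method='kde'.
    """
    if len(dist) < 50:
        raise ValueError(f"need >= 50 values to fit peaks, got {len(dist)}")
    rng = np.random.default_rng(seed)
    values = dist.values[dist.values > 0]
    weights = dist.weights[dist.values > 0]
    if len(values) < 50:
        raise ValueError("need >= 50 positive Ks values to fit peaks on a log scale")
    if not np.allclose(weights, weights[0]):
        p = weights / weights.sum()
        idx = rng.choice(len(values), size=len(values), p=p)
        values = values[idx]
    x = np.log(values).reshape(-1, 1)
    try:
        best = None
        best_bic = math.inf
        for k in range(1, max_components + 1):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=3,
                random_state=int(rng.integers(0, 2**31 - 1)),
                reg_covar=1e-6,
            ).fit(x)
            bic = gm.bic(x)
            if bic < best_bic:
                best, best_bic = gm, bic
        if best is None or not best.converged_:
            raise RuntimeError("mixture fit did not converge")
        peaks = [
            Peak(float(np.exp(m[0])), float(w), "gmm")
            for m, w in zip(best.means_, best.weights_)
        ]
        return sorted(peaks, key=lambda p: p.modal_ks)
    except (RuntimeError, ValueError, np.linalg.LinAlgError):
        return _kde_peaks(values.ravel())


def _kde_peaks(values: np.ndarray) -> list[Peak]:
    logv = np.log(values)
    kde = gaussian_kde(logv, bw_method="silverman")
    grid = np.linspace(logv.min() - 0.5, logv.max() + 0.5, 512)
    dens = kde(grid)
    maxima = [
        i for i in range(1, len(grid) - 1) if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    if not maxima:
        maxima = [int(np.argmax(dens))]
    total = dens[maxima].sum()
    return sorted(
        (Peak(float(np.exp(grid[i])), float(dens[i] / total), "kde") for i in maxima),
        key=lambda p: p.modal_ks,
    )


def ks_to_time(ks: float, rate_r: float = DEFAULT_RATE) -> float:
    """Convert a synonymous divergence to million years: T = Ks/(2r)."""
    if ks < 0:
        raise ValueError("ks must be >= 0")
    if rate_r <= 0:
        raise ValueError("rate_r must be > 0")
    return ks / (2.0 * rate_r) / 1e6


def fit_wgd_events(
    dist: KsDistribution,
    rate_r: float = DEFAULT_RATE,
    max_components: int = 3,
    seed: int = 0,
    labels: Iterable[str] | None = None,
) -> list[WgdEvent]:
    """Detect peaks and convert each modal Ks to an absolute age."""
    peaks = detect_peaks(dist, max_components=max_components, seed=seed)
    labels = list(labels) if labels is not None else [f"event{i+1}" for i in range(len(peaks))]
    events = []
    for label, p in zip(labels, peaks):
        events.append(
            WgdEvent(label, p.modal_ks, p.mass, rate_r, ks_to_time(p.modal_ks, rate_r))
        )
    return events


def date_ltr(
    element_id: str, ltr5: str, ltr3: str, rate_r: float = DEFAULT_RATE
) -> LtrElement:
    """Date an LTR retrotransposon insertion from its terminal-repeat divergence.

    The two LTRs are identical at insertion; their K2P distance d gives the
    insertion age T = d/(2r).  Saturated distances yield no time (flagged).
    """
    if not ltr5 or not ltr3:
        raise ValueError("both LTR sequences must be nonempty")
    dist = k2p(ltr5, ltr3)
    t = None if dist.status == "saturated" else ks_to_time(dist.d, rate_r)
    return LtrElement(element_id, ltr5, ltr3, dist, rate_r, t)


def plot_distribution(dist: KsDistribution, peaks: list[Peak] | None = None, path=None):
    """Histogram of the Ks distribution with optional peak markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(dist.values, bins=50, weights=dist.weights, color="steelblue", alpha=0.8)
    if peaks:
        for p in peaks:
            ax.axvline(p.modal_ks, color="firebrick", linestyle="--")
    ax.set_xlabel("Ks (synonymous substitutions per site)")
    ax.set_ylabel("weighted pairs")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
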