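"""Hierarchical bootstrap for nested (site -> neuron) data.

Neural data are nested: neurons within an imaging site are not
independent samples.  The hierarchical bootstrap respects this by
resampling sites with replacement first, then neurons within each drawn
site, and taking the grand mean over the drawn neurons.  Repeating this
N times gives a bootstrap distribution of the mean; its 15.8th-84.2nd
percentile interval is the 1 SD (68%) standard-error band.  Condition
comparisons use independent hierarchical resampling of each condition
and per-bin sign fractions of the difference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NestedSamples",
    "BootstrapResult",
    "hierarchical_bootstrap_mean",
    "bootstrap_se_band",
    "compare_conditions",
]


@dataclass
class NestedSamples:
    """Per-neuron trial-averaged values grouped by imaging site.

    Each element of ``sites`` is an array of shape (n_neurons,) for
    scalar summaries or (n_neurons, n_bins) for time-binned vectors; all
    sites must share the time axis.
    """

    sites: list[np.ndarray]
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sites) == 0:
            raise ValueError("need at least one site")
        self.sites = [np.atleast_1d(np.asarray(s, float)) for s in self.sites]
        n_bins = {s.shape[1] for s in self.sites if s.ndim == 2}
        if len(n_bins) > 1:
            raise ValueError("sites have inconsistent time axes")
        for s in self.sites:
            if s.shape[0] == 0:
                raise ValueError("empty site rejected")
        if not self.site_ids:
            self.site_ids = [f"site{i}" for i in range(len(self.sites))]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_bins(self) -> int:
        s = self.sites[0]
        return s.shape[1] if s.ndim == 2 else 1

    @classmethod
    def from_frame(cls, df) -> "NestedSamples":
        """Build from a long table with columns site_id, roi_id, bin_index, value."""
        sites = []
        ids = []
        for site_id, g in df.groupby("site_id", sort=True):
            pivot = g.pivot_table(index="roi_id", columns="bin_index",
                                  values="value", sort=True)
            arr = pivot.to_numpy(float)
            sites.append(arr[:, 0] if arr.shape[1] == 1 else arr)
            ids.append(str(site_id))
        return cls(sites=sites, site_ids=ids)


@dataclass
class BootstrapResult:
    distribution: np.ndarray  # (n_boot,) or (n_boot, n_bins)
    n_boot: int
    seed: int | None
    mean: np.ndarray = None
    lo: np.ndarray = None  # 15.8th percentile
    hi: np.ndarray = None  # 84.2nd percentile


def hierarchical_bootstrap_mean(data: NestedSamples, n_boot: int = 10000,
                                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Bootstrap distribution of the grand mean under site->neuron resampling.

    Each replicate draws ``n_sites`` sites with replacement, then, within
    every drawn site, as many neurons with replacement as that site
    contributed, and averages over all drawn neurons.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = data.sites
    n_sites = len(sites)
    if n_sites == 1:
        # resampling one site with replacement always returns that site:
        # only the neuron level varies, which vectorizes directly
        vals = sites[0]
        n = vals.shape[0]
        idx = rng.integers(0, n, size=(n_boot, n))
        return vals[idx].mean(axis=1)
    vector = sites[0].ndim == 2
    n_bins = data.n_bins
    out = np.empty((n_boot, n_bins)) if vector else np.empty(n_boot)
    site_draws = rng.integers(0, n_sites, size=(n_boot, n_sites))
    for b in range(n_boot):
        total = np.zeros(n_bins) if vector else 0.0
        count = 0
        for s in site_draws[b]:
            vals = sites[s]
            n = vals.shape[0]
            idx = rng.integers(0, n, size=n)
            total = total + vals[idx].sum(axis=0)
            count += n
        out[b] = total / count
    return out


def bootstrap_se_band(distribution: np.ndarray, n_boot: int | None = None,
                      seed: int | None = None) -> BootstrapResult:
    """Mean and 1 SD (68%) percentile band of a bootstrap distribution.

    The band is the 15.8th to 84.2nd percentile interval, computed per
    time bin for vector-valued replicates.
    """
    dist = np.asarray(distribution, float)
    if dist.size == 0:
        raise ValueError("empty bootstrap distribution")
    mean = dist.mean(axis=0)
    lo = np.percentile(dist, 15.8, axis=0)
    hi = np.percentile(dist, 84.2, axis=0)
    return BootstrapResult(distribution=dist, n_boot=dist.shape[0] if n_boot is None else n_boot,
                           seed=seed, mean=mean, lo=lo, hi=hi)


def compare_conditions(a: NestedSamples, b: NestedSamples, n_boot: int = 10000,
                       alpha: float = 0.01, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin bootstrap comparison of two conditions.

    Builds the bootstrap distribution of ``mean(a) - mean(b)`` with
    independent hierarchical resampling of each condition; the two-sided
    p value per bin is ``2 * min(frac <= 0, frac >= 0)`` of the
    difference distribution (resolution 1/n_boot), and the significance
    mask is ``p < alpha`` with no across-bin correction.
    """
    if a.n_bins != b.n_bins:
        raise ValueError("conditions have mismatched time axes")
    rng = np.random.default_rng(seed)
    da = hierarchical_bootstrap_mean(a, n_boot, rng)
    db = hierarchical_bootstrap_mean(b, n_boot, rng)
    diff = np.atleast_2d((da - db).T).T  # (n_boot, n_bins)
    frac_le = (diff <= 0).mean(axis=0)
    frac_ge = (diff >= 0).mean(axis=0)
    p = np.minimum(1.0, 2.0 * np.minimum(frac_le, frac_ge))
    p = np.maximum(p, 1.0 / n_boot)
    return p, p < alpha
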