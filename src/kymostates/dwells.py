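"""Dwell-time statistics from idealized traces.

Extraction keeps track of boundary censoring (the first and last
sojourns of a trace are truncated by the observation window and are
excluded from means and fits), display follows single-channel
conventions (logarithmic binning, square-root-ordinate Sigworth
transform), and multi-exponential mixtures are fitted by maximum
likelihood with a left-truncation correction at the detection floor,
with reduced chi-square guarding against overfitting of the component
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import ConfigurationError, InsufficientDataError
from .states import IdealizedTrace

__all__ = [
    "DwellRecord",
    "LogBinned",
    "SigworthDisplay",
    "ExpMixtureFit",
    "TransitionTile",
    "PathwayStats",
    "extract_dwells",
    "uncensored",
    "log_bin",
    "sigworth_transform",
    "fit_exp_mixture",
    "dwell_height_density",
    "transition_tiles",
    "pathway_statistics",
    "state_names",
]

#: shortest reportable dwell: two scan lines at the default 3.3 ms period
MIN_DURATION = 0.0066


def state_names(n_states: int) -> dict:
    """Conventional names for height-ordered integer state labels."""
    if n_states == 1:
        return {0: "out"}
    if n_states == 2:
        return {0: "in", 1: "out"}
    if n_states == 3:
        return {0: "in", 1: "int", 2: "out"}
    names = {0: "in", n_states - 1: "out"}
    for i in range(1, n_states - 1):
        names[i] = f"int{i}"
    return names


@dataclass
class DwellRecord:
    """One sojourn in one state with its neighbours and censoring flags."""

    state: object
    duration: float
    t_start: float
    t_end: float
    height: float
    prev: Optional[object] = None
    next: Optional[object] = None
    left_censored: bool = False
    right_censored: bool = False
    trace_id: Optional[int] = None

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


def extract_dwells(
    ideal: IdealizedTrace,
    trace_id: Optional[int] = None,
    t_offset: float = 0.0,
) -> list:
    """One :class:`DwellRecord` per maximal constant-state run.

    The first record is left-censored and the last right-censored (a
    single-state trace yields one fully censored record).  Durations are
    integer multiples of the sampling period, and the censored plus
    uncensored durations add up to the trace duration exactly.
    """
    if ideal.sampling_period is None:
        raise ConfigurationError("idealized trace lacks a sampling period")
    period = ideal.sampling_period
    bounds = ideal.segment_bounds
    labels = ideal.segment_labels
    records = []
    n_seg = labels.size
    for i in range(n_seg):
        records.append(
            DwellRecord(
                state=int(labels[i]),
                duration=float((bounds[i + 1] - bounds[i]) * period),
                t_start=t_offset + float(bounds[i] * period),
                t_end=t_offset + float(bounds[i + 1] * period),
                height=float(ideal.segment_means[i]),
                prev=int(labels[i - 1]) if i > 0 else None,
                next=int(labels[i + 1]) if i < n_seg - 1 else None,
                left_censored=i == 0,
                right_censored=i == n_seg - 1,
                trace_id=trace_id,
            )
        )
    return records


def uncensored(records: Sequence[DwellRecord]) -> list:
    return [r for r in records if not r.censored]


@dataclass
class LogBinned:
    """Counts in geometric duration bins."""

    counts: np.ndarray
    edges: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _durations(dwells) -> np.ndarray:
    if len(dwells) and isinstance(dwells[0], DwellRecord):
        return np.array([r.duration for r in dwells], dtype=float)
    return np.asarray(dwells, dtype=float)


def log_bin(dwells, bins_per_decade: int = 10) -> LogBinned:
    """Histogram dwell durations into geometric (log-spaced) bins.

    Bin edges land on the decimal-logarithm grid with
    ``bins_per_decade`` bins per decade; the grid is extended so every
    input falls inside, hence counts always sum to the input size.
    """
    d = _durations(dwells)
    if d.size == 0:
        raise InsufficientDataError("no dwells to bin")
    if np.any(d <= 0):
        raise ConfigurationError("durations must be positive")
    lo = np.floor(np.log10(d.min()) * bins_per_decade) / bins_per_decade
    hi = np.ceil(np.log10(d.max()) * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    n_bins = int(round((hi - lo) * bins_per_decade))
    edges = 10 ** (lo + np.arange(n_bins + 1) / bins_per_decade)
    edges[0] = min(edges[0], d.min()) * (1 - 1e-12)
    edges[-1] = max(edges[-1], d.max())
    counts, _ = np.histogram(d, bins=edges)
    return LogBinned(counts=counts, edges=edges)


@dataclass
class SigworthDisplay:
    """Square-root-ordinate, log-abscissa dwell-time distribution."""

    log10_duration: np.ndarray
    amplitude: np.ndarray  # sqrt of the probability density of log10(t)


def sigworth_transform(binned: LogBinned) -> SigworthDisplay:
    """Square-root-density display of a log-binned dwell histogram.

    The ordinate is the square root of the per-bin probability density
    of the log10 duration, which turns each exponential component into
    a peak at its time constant; empty bins map to zero.  The display is
    invariant to rescaling all counts.
    """
    widths = np.diff(np.log10(binned.edges))
    n = max(binned.n, 1)
    density = binned.counts / (n * widths)
    return SigworthDisplay(
        log10_duration=np.log10(binned.centers),
        amplitude=np.sqrt(density),
    )


@dataclass
class ExpMixtureFit:
    """Maximum-likelihood exponential-mixture fit of dwell durations."""

    components: list  # (tau_s, fraction), taus strictly increasing
    reduced_chi2: float
    n_dwells: int
    min_duration: float
    empirical_mean: float
    chi2_by_k: dict = field(default_factory=dict)

    def __post_init__(self):
        taus = [t for t, _ in self.components]
        fracs = [w for _, w in self.components]
        if any(t <= 0 for t in taus) or any(b <= a for a, b in zip(taus[:-1], taus[1:])):
            raise ConfigurationError("taus must be positive and strictly increasing")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ConfigurationError("fractions must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for t, _ in self.components])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([w for _, w in self.components])

    @property
    def mixture_mean(self) -> float:
        """Implied mean dwell of the untruncated mixture, sum(w * tau)."""
        return float(np.sum(self.taus * self.fractions))


def _em_exponential(s: np.ndarray, k: int, n_iter: int = 500, tol: float = 1e-10):
    """EM fit of a k-component exponential mixture on shifted data."""
    mean = float(s.mean())
    tau_floor = max(1e-4 * mean, 1e-9)
    if k == 1:
        tau = max(mean, tau_floor)
        ll = float(np.sum(-np.log(tau) - s / tau))
        return np.array([tau]), np.array([1.0]), ll
    best = None
    for spread in (4.0, 10.0, 2.0):
        taus = np.clip(mean * np.geomspace(1.0 / spread, spread, k), tau_floor, None)
        w = np.full(k, 1.0 / k)
        prev_ll = -np.inf
        for _ in range(n_iter):
            logp = np.log(w)[None, :] - np.log(taus)[None, :] - s[:, None] / taus[None, :]
            norm_ = logsumexp(logp, axis=1)
            r = np.exp(logp - norm_[:, None])
            ll = float(norm_.sum())
            rk = r.sum(axis=0)
            rk = np.clip(rk, 1e-300, None)
            taus = np.clip((r * s[:, None]).sum(axis=0) / rk, tau_floor, None)
            w = rk / s.size
            if ll - prev_ll < tol * max(abs(ll), 1.0):
                prev_ll = ll
                break
            prev_ll = ll
        if best is None or prev_ll > best[2]:
            best = (taus, w, prev_ll)
    return best


def _truncated_cdf(t: np.ndarray, taus, w_shift, m: float) -> np.ndarray:
    """CDF of the left-truncated mixture in the original time variable."""
    t = np.asarray(t, dtype=float)
    s = np.clip(t - m, 0.0, None)
    surv = np.sum(w_shift[None, :] * np.exp(-s[:, None] / taus[None, :]), axis=1)
    return 1.0 - surv


def _chi2_reduced(d, taus, w_shift, m, k, bins_per_decade, time_quantum):
    binned = log_bin(d, bins_per_decade)
    edges = binned.edges
    if time_quantum and time_quantum > 0:
        # snap edges to the half-sample grid so the duration quantisation
        # does not inflate chi-square at short dwells
        snapped = (np.round(edges / time_quantum - 0.5) + 0.5) * time_quantum
        edges = np.unique(np.clip(snapped, 0.5 * time_quantum, None))
        if edges.size < 3:
            return float("nan")
        edges[0] = min(edges[0], d.min() * (1 - 1e-12))
        edges[-1] = max(edges[-1], d.max())
    counts, _ = np.histogram(d, bins=edges)
    cdf = _truncated_cdf(edges, taus, w_shift, m)
    expected = d.size * np.diff(cdf)
    use = expected >= 5.0
    dof = int(use.sum()) - (2 * k - 1) - 1
    if dof < 1:
        return float("nan")
    chi2 = float(np.sum((counts[use] - expected[use]) ** 2 / expected[use]))
    return chi2 / dof


def fit_exp_mixture(
    dwells,
    max_components: int = 3,
    min_duration: float = MIN_DURATION,
    *,
    bins_per_decade: int = 10,
    improvement_ratio: float = 0.8,
    min_dwells: int = 50,
    time_quantum: Optional[float] = None,
) -> ExpMixtureFit:
    """Fit dwell durations with an exponential mixture, guarding k.

    Only uncensored dwells at least ``min_duration`` long enter the fit;
    the likelihood is left-truncated at ``min_duration`` (by
    memorylessness, the shifted durations are again an exponential
    mixture with reweighted fractions) so the detection floor does not
    bias the time constants.  Components are added while the reduced
    chi-square on the log-binned histogram improves by more than
    ``1 - improvement_ratio``; otherwise the simpler model is kept.

    ``time_quantum`` is the duration discretisation step (the sampling
    period); when omitted it is inferred from the data.
    """
    if len(dwells) and isinstance(dwells[0], DwellRecord):
        d = np.array([r.duration for r in dwells if not r.censored], dtype=float)
    else:
        d = np.asarray(dwells, dtype=float)
    d = d[d >= min_duration]
    if d.size < min_dwells:
        raise InsufficientDataError(
            f"need at least {min_dwells} uncensored dwells >= min_duration, got {d.size}"
        )
    if time_quantum is None:
        uniq = np.unique(d)
        gaps = np.diff(uniq)
        time_quantum = float(gaps.min()) if gaps.size else 0.0
        if time_quantum < 1e-5:  # effectively continuous data
            time_quantum = 0.0
    s = d - min_duration

    fits = {}
    chi2_by_k = {}
    for k in range(1, max_components + 1):
        taus, w_shift, _ = _em_exponential(s, k)
        order = np.argsort(taus)
        taus, w_shift = taus[order], w_shift[order]
        fits[k] = (taus, w_shift)
        chi2_by_k[k] = _chi2_reduced(
            d, taus, w_shift, min_duration, k, bins_per_decade, time_quantum
        )

    chosen = max_components
    for k in range(1, max_components):
        c_k, c_next = chi2_by_k[k], chi2_by_k[k + 1]
        if np.isnan(c_next) or (not np.isnan(c_k) and c_next > improvement_ratio * c_k):
            chosen = k
            break
    taus, w_shift = fits[chosen]
    # undo the truncation reweighting to report untruncated fractions
    w = w_shift * np.exp(min_duration / taus)
    w = w / w.sum()
    # merge indistinguishable components (EM can duplicate a tau)
    comps: list = []
    for t, f in zip(taus, w):
        if comps and t <= comps[-1][0] * (1 + 1e-9):
            comps[-1] = (comps[-1][0], comps[-1][1] + f)
        else:
            comps.append((float(t), float(f)))
    return ExpMixtureFit(
        components=comps,
        reduced_chi2=float(chi2_by_k[chosen]),
        n_dwells=int(d.size),
        min_duration=float(min_duration),
        empirical_mean=float(d.mean()),
        chi2_by_k=chi2_by_k,
    )


@dataclass
class DwellHeightDensity:
    """Joint log-duration x height histogram with per-state Gaussian fits."""

    hist: np.ndarray
    duration_edges: np.ndarray
    height_edges: np.ndarray
    state_gaussians: dict  # state -> (mean_nm, sigma_nm, n)


def dwell_height_density(
    records: Sequence[DwellRecord],
    bins_per_decade: int = 10,
    height_bins: int = 30,
) -> DwellHeightDensity:
    """Dwell-time-versus-height density with per-state height Gaussians."""
    unc = uncensored(records)
    if not unc:
        raise InsufficientDataError("no uncensored dwells")
    d = np.array([r.duration for r in unc])
    h = np.array([r.height for r in unc])
    dur_edges = log_bin(d, bins_per_decade).edges
    h_lo, h_hi = h.min(), h.max()
    pad = 0.05 * max(h_hi - h_lo, 1e-6)
    height_edges = np.linspace(h_lo - pad, h_hi + pad, height_bins + 1)
    hist, _, _ = np.histogram2d(d, h, bins=[dur_edges, height_edges])
    gaussians = {}
    for state in sorted({r.state for r in unc}):
        vals = h[np.array([r.state == state for r in unc])]
        mu, sig = norm.fit(vals)
        gaussians[state] = (float(mu), float(sig), int(vals.size))
    return DwellHeightDensity(
        hist=hist,
        duration_edges=dur_edges,
        height_edges=height_edges,
        state_gaussians=gaussians,
    )


@dataclass
class TransitionTile:
    """Consecutive-dwell pairs for one ordered state transition."""

    from_state: object
    to_state: object
    pairs: np.ndarray  # (n, 2): (initial dwell, final dwell), seconds

    @property
    def n(self) -> int:
        return int(self.pairs.shape[0])

    def log_correlation(self) -> float:
        """Pearson correlation of log-durations of consecutive dwells."""
        if self.n < 3:
            return float("nan")
        a, b = np.log(self.pairs[:, 0]), np.log(self.pairs[:, 1])
        return float(np.corrcoef(a, b)[0, 1])


def transition_tiles(dwell_sequences: Sequence[Sequence[DwellRecord]]) -> dict:
    """Collect consecutive uncensored dwell pairs per ordered transition."""
    pairs: dict = {}
    for seq in dwell_sequences:
        for a, b in zip(seq[:-1], seq[1:]):
            if a.censored or b.censored:
                continue
            pairs.setdefault((a.state, b.state), []).append((a.duration, b.duration))
    return {
        key: TransitionTile(key[0], key[1], np.array(val, dtype=float))
        for key, val in pairs.items()
    }


@dataclass
class PathwayStats:
    """Counts and dwell means of intermediate-state excursion pathways.

    Pathways are keyed ``(start, end)`` by the flanking states of an
    intermediate visit: ``start == end`` is a failed excursion, the
    others complete membrane crossings.
    """

    counts: dict
    intermediate_dwell_means: dict
    initial_dwell_means: dict

    @property
    def failed_count(self) -> int:
        return sum(n for (a, b), n in self.counts.items() if a == b)

    @property
    def complete_count(self) -> int:
        return sum(n for (a, b), n in self.counts.items() if a != b)

    @property
    def failed_to_complete_ratio(self) -> float:
        c = self.complete_count
        return self.failed_count / c if c else float("inf")


def pathway_statistics(
    dwell_sequences: Sequence[Sequence[DwellRecord]],
    intermediate: object = 1,
) -> PathwayStats:
    """Classify intermediate-state visits into failed and complete pathways.

    For every interior intermediate dwell the flanking states define the
    pathway (out->int->out and in->int->in are failed excursions;
    out->int->in and in->int->out complete crossings).  Initial-state
    dwell means only pool uncensored initial dwells.
    """
    counts: dict = {}
    int_dwells: dict = {}
    init_dwells: dict = {}
    for seq in dwell_sequences:
        for i in range(1, len(seq) - 1):
            r = seq[i]
            if r.state != intermediate or r.censored:
                continue
            key = (seq[i - 1].state, seq[i + 1].state)
            counts[key] = counts.get(key, 0) + 1
            int_dwells.setdefault(key, []).append(r.duration)
            if not seq[i - 1].censored:
                init_dwells.setdefault(key, []).append(seq[i - 1].duration)
    return PathwayStats(
        counts=counts,
        intermediate_dwell_means={k: float(np.mean(v)) for k, v in int_dwells.items()},
        initial_dwell_means={k: float(np.mean(v)) for k, v in init_dwells.items()},
    )
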