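"""Synthetic single-transporter data with the statistical structure of
HS-AFM line-scanning recordings.

The generator produces, in increasing order of realism:

* semi-Markov state sequences (:func:`simulate_state_sequence`) — each
  state draws its dwell from an exponential mixture, then jumps to a
  neighbour according to a row-stochastic transition matrix;
* noisy sampled height/time traces (:func:`render_height_trace`);
* full line-scan kymographs with lateral protomer profiles, stage drift
  and pixel noise (:func:`render_kymograph`);
* membrane topography images for packing analysis
  (:func:`render_topography_image`).

Two condition presets mirror the elevator-transporter kinetics the
analysis is designed for: ``apo`` (no substrate; mean dwells
out 347 ms / in 328 ms / intermediate 175 ms, 78 % of out/in exits go
directly to the opposite side) and ``transport`` (saturating Na+ and
aspartate; 510 / 341 / 297 ms and 58 % direct).  The elevator amplitude
between the outward- and inward-facing states is 1.2 nm with the
intermediate level midway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .containers import HeightTrace, Kymograph, TopographyImage, TraceTruth, n_samples_for
from .errors import ConfigurationError

__all__ = [
    "StateSpec",
    "SchemeConfig",
    "KymoSceneConfig",
    "apo_scheme",
    "transport_scheme",
    "two_state_scheme",
    "three_state_scheme",
    "simulate_state_sequence",
    "simulate_population",
    "render_height_trace",
    "render_kymograph",
    "render_topography_image",
    "ridge_profile",
]

#: default state heights above the membrane baseline (nm): the protomer
#: protrudes ~2 nm in the outward-facing state and the elevator travels
#: 1.2 nm, with the intermediate level midway.
DEFAULT_HEIGHTS = {"in": 0.8, "int": 1.4, "out": 2.0}


@dataclass(frozen=True)
class StateSpec:
    """One conformational state: a label, a mean height and dwell kinetics.

    ``dwell_mixture`` is a sequence of ``(tau, weight)`` pairs defining an
    exponential mixture; weights must sum to one and every tau must be
    positive.  The mixture mean is ``sum(w * tau)``.
    """

    label: str
    height: float
    dwell_mixture: tuple = ((0.3, 1.0),)

    def __post_init__(self):
        mix = tuple((float(t), float(w)) for t, w in self.dwell_mixture)
        object.__setattr__(self, "dwell_mixture", mix)
        if any(t <= 0 for t, _ in mix):
            raise ConfigurationError(f"state {self.label!r}: dwell tau must be positive")
        if any(w < 0 for _, w in mix):
            raise ConfigurationError(f"state {self.label!r}: weights must be non-negative")
        if abs(sum(w for _, w in mix) - 1.0) > 1e-9:
            raise ConfigurationError(f"state {self.label!r}: mixture weights must sum to 1")

    @property
    def mean_dwell(self) -> float:
        return sum(t * w for t, w in self.dwell_mixture)

    def sample_dwell(self, rng: np.random.Generator) -> float:
        taus = [t for t, _ in self.dwell_mixture]
        weights = [w for _, w in self.dwell_mixture]
        if len(taus) == 1:
            return float(rng.exponential(taus[0]))
        k = rng.choice(len(taus), p=weights)
        return float(rng.exponential(taus[k]))


@dataclass
class SchemeConfig:
    """Kinetic scheme generating a semi-Markov state sequence.

    Parameters
    ----------
    states
        States ordered by strictly increasing height (inward < intermediate
        < outward for the three-state scheme).
    transition_probs
        Row-stochastic matrix ``P[i, j]`` of jump probabilities between the
        states in listed order, with zero diagonal.
    active_fraction
        Probability that a protomer is dynamic at all; inactive protomers
        rest in the highest (outward-facing) state.
    temperature
        Kelvin; only used when exporting energies in absolute units.
    return_probability
        Optional memory for exits from the intermediate state of a
        three-state scheme: the probability that an excursion to the
        intermediate returns to the side it came from (a "failed"
        excursion).  When set it overrides the intermediate row of
        ``transition_probs`` for all but the first segment.
    """

    states: list
    transition_probs: np.ndarray
    active_fraction: float = 1.0
    temperature: float = 298.0
    return_probability: Optional[float] = None
    intermediate_label: str = "int"
    condition: Optional[str] = None

    def __post_init__(self):
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        n = len(self.states)
        heights = [s.height for s in self.states]
        if any(b <= a for a, b in zip(heights[:-1], heights[1:])):
            raise ConfigurationError("state heights must be strictly increasing")
        if self.transition_probs.shape != (n, n):
            raise ConfigurationError("transition matrix shape must match state count")
        if np.any(self.transition_probs < 0):
            raise ConfigurationError("transition probabilities must be non-negative")
        if np.any(np.abs(self.transition_probs.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("transition matrix rows must sum to 1")
        if np.any(np.diag(self.transition_probs) != 0):
            raise ConfigurationError("self-transitions are not allowed")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ConfigurationError("active_fraction must lie in [0, 1]")
        if self.return_probability is not None:
            if n != 3 or self.states[1].label != self.intermediate_label:
                raise ConfigurationError(
                    "return_probability requires a three-state scheme with the "
                    "intermediate listed second"
                )
            if not 0.0 <= self.return_probability <= 1.0:
                raise ConfigurationError("return_probability must lie in [0, 1]")

    @property
    def labels(self) -> list:
        return [s.label for s in self.states]

    @property
    def heights(self) -> dict:
        return {s.label: s.height for s in self.states}

    @property
    def amplitude(self) -> float:
        """Height difference between the highest and lowest states (nm)."""
        return self.states[-1].height - self.states[0].height

    def mean_dwells(self) -> dict:
        return {s.label: s.mean_dwell for s in self.states}

    def embedded_stationary(self) -> np.ndarray:
        """Stationary distribution of the embedded jump chain."""
        p = self.transition_probs
        n = p.shape[0]
        a = np.vstack([p.T - np.eye(n), np.ones(n)])
        b = np.concatenate([np.zeros(n), [1.0]])
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0, None)
        return pi / pi.sum()

    def occupancies(self) -> np.ndarray:
        """Long-run fraction of time spent in each state.

        The time-weighted stationary distribution: jump-chain visit
        frequencies weighted by the mean dwell of each state.
        """
        pi = self.embedded_stationary()
        tau = np.array([s.mean_dwell for s in self.states])
        occ = pi * tau
        return occ / occ.sum()


def _direct_matrix(direct_prob: float) -> np.ndarray:
    """Transition matrix for states (in, int, out) with a given direct
    out<->in probability; exits from the intermediate split evenly."""
    q = 1.0 - direct_prob
    return np.array(
        [
            [0.0, q, direct_prob],
            [0.5, 0.0, 0.5],
            [direct_prob, q, 0.0],
        ]
    )


def three_state_scheme(
    mean_in: float,
    mean_int: float,
    mean_out: float,
    direct_prob: float,
    *,
    heights: Optional[dict] = None,
    active_fraction: float = 1.0,
    return_probability: Optional[float] = 2.0 / 3.0,
    condition: Optional[str] = None,
) -> SchemeConfig:
    """Build a three-state elevator scheme from mean dwells (seconds)."""
    h = dict(DEFAULT_HEIGHTS if heights is None else heights)
    states = [
        StateSpec("in", h["in"], ((mean_in, 1.0),)),
        StateSpec("int", h["int"], ((mean_int, 1.0),)),
        StateSpec("out", h["out"], ((mean_out, 1.0),)),
    ]
    return SchemeConfig(
        states,
        _direct_matrix(direct_prob),
        active_fraction=active_fraction,
        return_probability=return_probability,
        condition=condition,
    )


def two_state_scheme(
    mean_in: float,
    mean_out: float,
    *,
    height_in: float = 0.8,
    height_out: float = 2.0,
    active_fraction: float = 1.0,
    condition: Optional[str] = None,
) -> SchemeConfig:
    """Out/in alternation with no intermediate state."""
    states = [
        StateSpec("in", height_in, ((mean_in, 1.0),)),
        StateSpec("out", height_out, ((mean_out, 1.0),)),
    ]
    p = np.array([[0.0, 1.0], [1.0, 0.0]])
    return SchemeConfig(states, p, active_fraction=active_fraction, condition=condition)


def apo_scheme(active_fraction: float = 0.55) -> SchemeConfig:
    """No-substrate preset: fast cycling, intermediate rarely visited."""
    return three_state_scheme(
        0.328, 0.175, 0.347, 0.78, active_fraction=active_fraction, condition="apo"
    )


def transport_scheme(active_fraction: float = 0.23) -> SchemeConfig:
    """Saturating Na+/aspartate preset: slower, intermediate more populated."""
    return three_state_scheme(
        0.341, 0.297, 0.510, 0.58, active_fraction=active_fraction, condition="transport"
    )


def simulate_state_sequence(
    scheme: SchemeConfig,
    duration: float,
    seed=None,
    *,
    rng: Optional[np.random.Generator] = None,
) -> TraceTruth:
    """Draw a semi-Markov state sequence of the given total span.

    Dwells are sampled from each state's exponential mixture; the next
    state is drawn from the scheme's transition-probability row (or, when
    ``return_probability`` is set, exits from the intermediate state
    return to the previous side with that probability).  The final dwell
    is truncated at ``duration`` and flagged; the first and last dwells
    are boundary-censored by construction.  Identical seeds give
    identical sequences.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels_by_index = scheme.labels
    n = len(labels_by_index)
    occ = scheme.occupancies()
    state = int(rng.choice(n, p=occ))
    prev: Optional[int] = None
    int_index = 1 if scheme.return_probability is not None else -1

    times = [0.0]
    seg_labels: list = []
    t = 0.0
    while t < duration:
        seg_labels.append(state)
        t += scheme.states[state].sample_dwell(rng)
        times.append(t)
        if state == int_index and prev is not None:
            other = 2 if prev == 0 else 0
            nxt = prev if rng.random() < scheme.return_probability else other
        else:
            nxt = int(rng.choice(n, p=scheme.transition_probs[state]))
        prev, state = state, nxt

    change_times = np.array(times[1:-1], dtype=float)
    heights = np.array([scheme.states[i].height for i in seg_labels])
    return TraceTruth(
        change_times=change_times,
        state_labels=[labels_by_index[i] for i in seg_labels],
        segment_heights=heights,
        duration=float(duration),
        last_truncated=True,
        seed=seed if isinstance(seed, int) else None,
    )


def _inactive_truth(scheme: SchemeConfig, duration: float) -> TraceTruth:
    top = scheme.states[-1]
    return TraceTruth(
        change_times=np.empty(0),
        state_labels=[top.label],
        segment_heights=np.array([top.height]),
        duration=float(duration),
        active=False,
    )


def simulate_population(
    scheme: SchemeConfig,
    n_protomers: int,
    duration: float,
    seed=None,
) -> list:
    """Simulate a mixed active/inactive protomer population.

    Each protomer is dynamic with probability ``scheme.active_fraction``;
    inactive protomers rest in the outward-facing (highest) state.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    truths = []
    for child in ss.spawn(n_protomers):
        rng = np.random.default_rng(child)
        if rng.random() < scheme.active_fraction:
            truths.append(simulate_state_sequence(scheme, duration, rng=rng))
        else:
            truths.append(_inactive_truth(scheme, duration))
    return truths


def render_height_trace(
    truth: TraceTruth,
    noise_sigma: float,
    sampling_period: float = 0.0033,
    seed=None,
    *,
    heights: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> HeightTrace:
    """Sample a state sequence into a noisy height/time trace.

    One sample is taken per scan line at ``k * sampling_period`` for
    ``k = 0 .. n-1`` with the last sample strictly before the truth's
    duration, then i.i.d. zero-mean Gaussian noise of standard deviation
    ``noise_sigma`` is added.  The trace's signal-to-noise ratio is the
    out-in amplitude divided by ``noise_sigma``.
    """
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = n_samples_for(truth.duration, sampling_period)
    times = np.arange(n) * sampling_period
    if heights is None:
        ideal = truth.heights_at(times)
    else:
        ideal = np.array([heights[s] for s in truth.labels_at(times)], dtype=float)
    noisy = ideal if noise_sigma == 0 else ideal + rng.normal(0.0, noise_sigma, size=n)
    truth_out = replace(truth, sampling_period=float(sampling_period))
    return HeightTrace(times=times, heights=noisy, truth=truth_out)


def ridge_profile(offset, half_width: float, flat_halfwidth: float = 0.6) -> np.ndarray:
    """Lateral cross-section of a protomer ridge, normalised to peak 1.

    A raised-cosine bump with a small flat apex: the profile is 1 within
    ``flat_halfwidth`` of the centre (the tip-broadened apex, wide enough
    that the nearest pixel always records the full protomer height),
    decays smoothly, and reaches exactly 0 at ``half_width``.  Supports
    vanish beyond ``half_width`` so protomers spaced wider than twice the
    half-width never overlap.
    """
    d = np.abs(np.asarray(offset, dtype=float))
    if half_width <= flat_halfwidth:
        raise ConfigurationError("half_width must exceed flat_halfwidth")
    out = np.zeros_like(d)
    out[d <= flat_halfwidth] = 1.0
    ramp = (d > flat_halfwidth) & (d < half_width)
    x = (d[ramp] - flat_halfwidth) / (half_width - flat_halfwidth)
    out[ramp] = np.cos(0.5 * np.pi * x) ** 2
    return out


@dataclass
class KymoSceneConfig:
    """Geometry and noise of a synthetic line-scan scene.

    Protomer ridges sit ``spacing`` nm apart (default 5.7 nm, the
    inter-protomer distance within trimer-packed membranes), each with a
    smooth unimodal lateral profile of ``profile_width`` half-width.
    ``x_drift`` translates peak positions over time; ``y_drift`` moves
    the scan line off the protomer apex, attenuating the apparent height
    by the ridge cross-section at the drifted offset.
    """

    n_protomers: int = 7
    spacing: float = 5.7
    profile_width: float = 3.0
    flat_halfwidth: float = 0.6
    membrane_height: float = 0.0
    x_drift: float = 0.0
    y_drift: float = 0.0
    noise_sigma: float = 0.0
    pixel_size: float = 1.0
    line_period: float = 0.0033
    duration: float = 60.0
    margin: float = 8.0
    width: Optional[float] = None

    def __post_init__(self):
        if self.n_protomers < 1:
            raise ConfigurationError("need at least one protomer")
        if self.spacing <= 0 or self.line_period <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("spacing, line_period and pixel_size must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")
        if self.width is None:
            self.width = 2 * self.margin + (self.n_protomers - 1) * self.spacing

    @property
    def n_pixels(self) -> int:
        return int(math.ceil(self.width / self.pixel_size))

    def base_positions(self) -> np.ndarray:
        """Initial protomer centres in nm from the left field edge."""
        return self.margin + self.spacing * np.arange(self.n_protomers)


def render_kymograph(
    scene: KymoSceneConfig,
    truths: Sequence[TraceTruth],
    seed=None,
    *,
    rng: Optional[np.random.Generator] = None,
) -> Kymograph:
    """Render per-protomer state sequences into a noisy kymograph.

    Each scan line is the membrane baseline plus the *envelope* (pixelwise
    maximum, as an AFM tip contours the tallest surface) of the protomer
    ridges.  Ridge peak heights follow each protomer's current state
    height; X drift shifts peak positions linearly in time and Y drift
    attenuates apparent heights through the lateral cross-section factor.
    """
    if len(truths) != scene.n_protomers:
        raise ConfigurationError("need one TraceTruth per protomer")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_lines = n_samples_for(scene.duration, scene.line_period)
    times = np.arange(n_lines) * scene.line_period
    n_px = scene.n_pixels
    px_centers = (np.arange(n_px) + 0.5) * scene.pixel_size

    x0 = scene.base_positions()
    x_final = x0 + scene.x_drift * times[-1]
    for xs in (x0, x_final):
        if np.any(xs < scene.profile_width) or np.any(xs > scene.width - scene.profile_width):
            raise ConfigurationError("protomer drifts outside the lateral field")

    atten = ridge_profile(
        scene.y_drift * times, scene.profile_width, scene.flat_halfwidth
    )
    grid = np.full((n_lines, n_px), float(scene.membrane_height))
    for p, truth in enumerate(truths):
        h = truth.heights_at(times) * atten  # (n_lines,)
        xp = x0[p] + scene.x_drift * times  # (n_lines,)
        profile = ridge_profile(
            px_centers[None, :] - xp[:, None], scene.profile_width, scene.flat_halfwidth
        )
        np.maximum(grid, scene.membrane_height + h[:, None] * profile, out=grid)
    if scene.noise_sigma > 0:
        grid += rng.normal(0.0, scene.noise_sigma, size=grid.shape)

    meta = {
        "line_period_s": scene.line_period,
        "pixel_size_nm": scene.pixel_size,
        "seed": seed if isinstance(seed, int) else None,
        "n_protomers": scene.n_protomers,
        "x_drift_nm_s": scene.x_drift,
        "y_drift_nm_s": scene.y_drift,
        "noise_sigma_nm": scene.noise_sigma,
        "base_positions_px": (x0 / scene.pixel_size - 0.5).tolist(),
    }
    truths = [replace(t, sampling_period=scene.line_period) for t in truths]
    return Kymograph(
        heights=grid,
        line_period=scene.line_period,
        pixel_size=scene.pixel_size,
        meta=meta,
        truths=list(truths),
    )


def render_topography_image(
    packing_fraction: float,
    membrane_height: float = 4.5,
    domain_height: float = 7.7,
    noise_sigma: float = 0.1,
    seed=None,
    *,
    shape=(256, 256),
    pixel_size: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> TopographyImage:
    """Membrane sheet with a single connected protein-packed domain.

    The domain is a disk whose pixel count matches ``packing_fraction`` of
    the image area exactly (radius chosen at the distance quantile), so
    thresholded area analysis recovers the requested fraction up to noise
    spill-over at the boundary.
    """
    if not 0.0 <= packing_fraction <= 1.0:
        raise ConfigurationError("packing_fraction must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    ny, nx = shape
    img = np.full(shape, float(membrane_height))
    if packing_fraction > 0:
        yy, xx = np.mgrid[0:ny, 0:nx]
        d2 = (yy - (ny - 1) / 2.0) ** 2 + (xx - (nx - 1) / 2.0) ** 2
        n_domain = int(round(packing_fraction * ny * nx))
        if n_domain > 0:
            cutoff = np.partition(d2.ravel(), n_domain - 1)[n_domain - 1]
            img[d2 <= cutoff] = domain_height
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=shape)
    return TopographyImage(heights=img, pixel_size=pixel_size)
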