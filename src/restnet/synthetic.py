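"""Synthetic cohorts with small-world coherence structure.

The base generator emulates what a band-limited lagged-coherence matrix from
a resting cortical network looks like: a dense, weakly coherent background
(every ROI pair shows some residual coherence) with a ring-lattice
neighborhood of strong coherences, a fraction of which is rewired to random
pairs — the classic lattice-with-shortcuts construction that yields
small-world topology. Group effects for case subjects are injected on the
weight matrix (fast) with an optional coupled-time-series path that
exercises the spectral pipeline end-to-end.

Effect targets map onto the graph indices they move:

- ``clustering``: scales the background coherences (triangle closure).
- ``path``: scales all weights globally (inverse-weight distances).
- ``diameter``: scales the rewired shortcut weights (tree elongation).
- ``hub_bc`` / ``nodal_bc:<ROI label>``: scales one ROI's row/column
  (hub formation in the spanning tree).

Direction +1 means the targeted index is larger in cases than controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from restnet.atlas import ROIAtlas, build_roi_atlas
from restnet.bands import BandSpec, default_bands
from restnet.connectivity import EpochSet
from restnet.graph import _ring_spans
from restnet.util import as_seed_sequence

_EFFECT_TARGETS = ("clustering", "path", "diameter", "hub_bc")


@dataclass(frozen=True)
class EffectSpec:
    """A group effect injected into case subjects in one band.

    Attributes
    ----------
    band : str
        Band name the effect applies to ("theta", ..., "beta2").
    target : str
        One of ``clustering``, ``path``, ``diameter``, ``hub_bc``, or
        ``nodal_bc:<ROI label>`` (e.g. ``"nodal_bc:BA20 R"``).
    magnitude : float
        Relative effect size (>= 0); the fractional change applied to the
        targeted weights.
    direction : int
        +1: targeted index larger in cases; -1: smaller.
    """

    band: str
    target: str
    magnitude: float
    direction: int = 1

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("effect magnitude must be >= 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        base = self.target.split(":", 1)[0]
        if base not in _EFFECT_TARGETS and base != "nodal_bc":
            raise ValueError(f"unknown effect target {self.target!r}")
        if base == "nodal_bc" and ":" not in self.target:
            raise ValueError("nodal_bc target needs an ROI label suffix")


@dataclass
class SyntheticCohort:
    """Per-subject, per-band coherence matrices with group labels."""

    matrices: dict[str, dict[str, np.ndarray]]
    groups: pd.Series
    atlas: ROIAtlas
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def subjects(self) -> list[str]:
        return list(self.matrices)

    @property
    def bands(self) -> list[str]:
        first = next(iter(self.matrices.values()))
        return list(first)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               size: int) -> np.ndarray:
    """Normal truncated to [0, 1] — the coherence range."""
    if sd <= 0:
        return np.full(size, np.clip(mean, 0.0, 1.0))
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                  random_state=rng)


def generate_sw_matrix(
    n: int = 84,
    k: int = 6,
    p_rewire: float = 0.1,
    weight_mean: float = 0.85,
    weight_sd: float = 0.01,
    noise_sd: float = 0.001,
    seed=None,
    background_mean: float = 0.01,
    background_sd: float = 0.003,
    return_masks: bool = False,
):
    """A small-world weighted coherence matrix on a ring lattice.

    Node pairs within ring span ``k`` carry strong coherence
    (truncated-normal around ``weight_mean``); each strong weight is
    relocated to a uniformly random background pair with probability
    ``p_rewire`` (swapping the two weights, so the weight multiset is
    unchanged by rewiring); all remaining pairs carry weak background
    coherence around ``background_mean``. Independent noise with standard
    deviation ``noise_sd`` is added everywhere and the matrix clipped to
    (0, 1] so the graph stays connected.

    Parameters
    ----------
    n, k : int
        Node count and lattice half-neighborhood (spans 1..k are strong).
    p_rewire : float
        Fraction of strong weights relocated; 0 = pure lattice, 1 = fully
        random placement.
    return_masks : bool
        Also return boolean upper-triangle masks ``(strong, rewired)``
        marking where the strong weights ended up and which of them were
        relocated (used by the effect injectors).

    Returns
    -------
    W : ndarray (n, n)
        Symmetric, zero diagonal, entries in (0, 1].
    """
    if not 0 <= p_rewire <= 1:
        raise ValueError("p_rewire must be in [0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    spans = _ring_spans(n)
    strong = spans <= k
    m = spans.size
    w = np.empty(m)
    w[strong] = _truncnorm(rng, weight_mean, weight_sd, int(strong.sum()))
    w[~strong] = _truncnorm(rng, background_mean, background_sd,
                            int((~strong).sum()))
    strong_now = strong.copy()
    rewired = np.zeros(m, dtype=bool)
    strong_idx = np.nonzero(strong)[0]
    move = strong_idx[rng.random(strong_idx.size) < p_rewire]
    bg_idx = np.nonzero(~strong)[0]
    if move.size and bg_idx.size:
        dest = rng.choice(bg_idx, size=move.size, replace=False)
        w[move], w[dest] = w[dest].copy(), w[move].copy()
        strong_now[move] = False
        strong_now[dest] = True
        rewired[dest] = True
    w = w + rng.normal(0.0, noise_sd, size=m)
    if np.ptp(w) < 1e-12:
        import warnings

        warnings.warn("all generated weights are equal; spanning-tree ties "
                      "will be broken lexicographically", stacklevel=2)
    w = np.clip(w, 1e-3, 1.0)
    W = np.zeros((n, n))
    W[iu] = w
    W = W + W.T
    if return_masks:
        return W, strong_now, rewired
    return W


def _apply_effects(
    W: np.ndarray,
    strong: np.ndarray,
    rewired: np.ndarray,
    effects: list[EffectSpec],
    atlas: ROIAtlas,
) -> np.ndarray:
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    w = W[iu].copy()
    for eff in effects:
        s = eff.direction * eff.magnitude
        base = eff.target.split(":", 1)[0]
        if base == "clustering":
            w[~strong] *= 1.0 + s
        elif base == "path":
            # global weight scaling: inverse-weight distances scale by
            # 1/(1 - s), normalized clustering is untouched
            w *= 1.0 - s
        elif base == "diameter":
            # shift shortcut weights relative to the strong-weight spread:
            # the spanning tree ranks edges, so only displacement on the
            # order of that spread changes how many shortcuts it keeps
            spread = w[strong].std()
            w[rewired] -= s * 2.0 * spread
        else:  # hub_bc / nodal_bc
            if base == "hub_bc" and ":" not in eff.target:
                hub = atlas.index("BA20 R") if n == len(atlas) else n // 2
            else:
                label = eff.target.split(":", 1)[1]
                hub = atlas.index(label)
            touches = (iu[0] == hub) | (iu[1] == hub)
            w[touches] *= 1.0 + s
    w = np.clip(w, 1e-3, 1.0)
    out = np.zeros_like(W)
    out[iu] = w
    return out + out.T


def generate_cohort(
    n_ctrl: int = 52,
    n_case: int = 19,
    effects: list[EffectSpec] | None = None,
    seed=None,
    bands: tuple[BandSpec, ...] | None = None,
    atlas: ROIAtlas | None = None,
    subject_jitter_sd: float = 0.02,
    **matrix_kwargs,
) -> SyntheticCohort:
    """Two-group cohort of per-band coherence matrices.

    Controls are drawn from the base small-world generator; cases from the
    same generator with the requested effects applied in their band.
    Between-subject variability enters as a per-subject jitter on the
    strong-weight mean (SD ``subject_jitter_sd``). Fully reproducible from
    ``seed``.
    """
    effects = list(effects or [])
    targets = [(e.band, e.target) for e in effects]
    if len(targets) != len(set(targets)):
        raise ValueError("duplicate effect targets")
    bands = bands if bands is not None else default_bands()
    atlas = atlas or build_roi_atlas()
    base_mean = matrix_kwargs.pop("weight_mean", 0.85)
    n = matrix_kwargs.pop("n", len(atlas))

    ss = as_seed_sequence(seed)
    subj_ids = [f"case{i + 1:02d}" for i in range(n_case)] + [
        f"ctrl{i + 1:02d}" for i in range(n_ctrl)
    ]
    labels = ["case"] * n_case + ["control"] * n_ctrl
    matrices: dict[str, dict[str, np.ndarray]] = {}
    for sid, grp, subj_ss in zip(subj_ids, labels, ss.spawn(len(subj_ids))):
        jit_rng = np.random.default_rng(subj_ss)
        subj_mean = base_mean + jit_rng.normal(0.0, subject_jitter_sd)
        per_band: dict[str, np.ndarray] = {}
        for band, band_ss in zip(bands, subj_ss.spawn(len(bands))):
            W, strong, rewired = generate_sw_matrix(
                n=n, weight_mean=subj_mean, seed=band_ss,
                return_masks=True, **matrix_kwargs,
            )
            if grp == "case":
                band_effects = [e for e in effects if e.band == band.name]
                if band_effects:
                    W = _apply_effects(W, strong, rewired, band_effects, atlas)
            per_band[band.name] = W
        matrices[sid] = per_band
    groups = pd.Series(labels, index=subj_ids, name="group")
    params = dict(
        n_ctrl=n_ctrl, n_case=n_case, weight_mean=base_mean,
        subject_jitter_sd=subject_jitter_sd,
        effects=[e.__dict__ for e in effects], **matrix_kwargs,
    )
    return SyntheticCohort(
        matrices=matrices, groups=groups, atlas=atlas, params=params,
        seed=seed,
    )


def _bandpass_noise(rng: np.random.Generator, n: int, f_lo: float,
                    f_hi: float, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    sos = sp_signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs,
                           output="sos")
    x = sp_signal.sosfilt(sos, rng.standard_normal(n + 512))[512:]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_coupled_timeseries(
    atlas: ROIAtlas,
    coupling: list[tuple] | None = None,
    fs: float = 250.0,
    n_epochs: int = 25,
    epoch_len: int = 1024,
    seed=None,
    common_source_strength: float = 0.0,
    common_source_band: tuple[float, float] = (4.0, 30.0),
) -> EpochSet:
    """Epoched ROI time series with controlled lagged couplings.

    Each channel is independent white noise; every coupling
    ``(pair, band, lag, strength)`` adds one band-limited stochastic
    oscillation to both channels of ``pair``, delayed by ``lag`` samples in
    the second channel (a nonzero lag creates genuine lagged coherence).
    ``common_source_strength`` mixes one shared band-limited source into
    every channel at zero lag, emulating the volume-conduction artifact
    that lagged coherence is designed to reject.

    Parameters
    ----------
    coupling : list of ((i, j), (f_lo, f_hi) or BandSpec, lag_samples, strength)
        Channel indices or atlas labels.
    """
    coupling = coupling or []
    rng = np.random.default_rng(seed)
    n_ch = len(atlas)

    def _chan(c) -> int:
        return c if isinstance(c, (int, np.integer)) else atlas.index(c)

    epochs = []
    for _ in range(n_epochs):
        X = rng.standard_normal((epoch_len, n_ch))
        for (ci, cj), band, lag, strength in coupling:
            i, j = _chan(ci), _chan(cj)
            if lag == 0:
                raise ValueError(
                    "coupling lag must be nonzero (use "
                    "common_source_strength for zero-lag mixing)"
                )
            f_lo, f_hi = (
                (band.f_lo, band.f_hi) if isinstance(band, BandSpec) else band
            )
            src = _bandpass_noise(rng, epoch_len + abs(int(lag)), f_lo, f_hi, fs)
            lag = int(lag)
            if lag > 0:
                X[:, i] += strength * src[lag:lag + epoch_len]
                X[:, j] += strength * src[:epoch_len]
            else:
                X[:, i] += strength * src[:epoch_len]
                X[:, j] += strength * src[-lag:-lag + epoch_len]
        if common_source_strength > 0:
            src = _bandpass_noise(rng, epoch_len, *common_source_band, fs)
            X += common_source_strength * src[:, None]
        epochs.append(X)
    return EpochSet(epochs=epochs, fs=fs)
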