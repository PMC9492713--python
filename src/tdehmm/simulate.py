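"""Ground-truth-labelled synthetic cohorts with Markov state switching.

Real source-space MEG at this scale is rarely shareable, so the package ships
a generator that emulates the features the downstream model cares about:

* hidden Markov switching between K states on fast (tens of ms) timescales,
* per-state oscillators with channel loadings (frequency-specific power),
* phase-coupled channel pairs within a state (frequency-specific coherence),
* per-subject amplitude variability and per-channel sign ambiguity,
* configurable two-group differences in state power, coupling and occupancy.

Oscillator phases reset with a fresh random draw at every state entry, so
states are genuinely non-phase-continuous: the spectral contrast between
states lives in the (auto)covariance structure, which is exactly what a
time-delay-embedded Gaussian observation model can capture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import SubjectTimeSeries

__all__ = [
    "Oscillator", "CoupledPair", "StateSpec", "GroupEffect", "CohortSpec",
    "GroundTruth", "simulate_state_path", "simulate_subject",
    "simulate_cohort", "corrupt_signs", "default_cohort_spec",
]


@dataclass(frozen=True)
class Oscillator:
    """A sinusoidal source: ``frequency`` in Hz, peak ``amplitude`` and a
    per-channel loading vector distributing it over channels."""
    frequency: float
    amplitude: float
    loadings: tuple

    def loading_array(self, n_channels: int) -> np.ndarray:
        arr = np.asarray(self.loadings, dtype=float)
        if arr.shape != (n_channels,):
            raise ValueError("loadings length must equal n_channels")
        return arr


@dataclass(frozen=True)
class CoupledPair:
    """Directed phase coupling: channel ``j`` receives a copy of channel
    ``i``'s oscillation advanced by ``phase_lag`` radians, mixed with weight
    ``strength`` in [0, 1] against channel ``j``'s own (independent-phase)
    oscillation."""
    i: int
    j: int
    phase_lag: float
    strength: float


@dataclass(frozen=True)
class StateSpec:
    state_id: int
    oscillators: tuple = ()
    coupled_pairs: tuple = ()
    noise_sd: float = 0.2
    pure_noise: bool = False

    def validate(self, fs: float, n_channels: int) -> None:
        if not self.oscillators and not self.pure_noise:
            raise ValueError(
                f"state {self.state_id}: needs an oscillator or pure_noise")
        for osc in self.oscillators:
            if not 0.0 < osc.frequency < fs / 2.0:
                raise ValueError(
                    f"state {self.state_id}: frequency {osc.frequency} Hz "
                    f"outside (0, fs/2) at fs={fs}")
            osc.loading_array(n_channels)
        for cp in self.coupled_pairs:
            if not 0.0 <= cp.strength <= 1.0:
                raise ValueError("coupling strength must be in [0, 1]")
            for c in (cp.i, cp.j):
                if not 0 <= c < n_channels:
                    raise ValueError(f"coupled channel {c} out of range")


@dataclass(frozen=True)
class GroupEffect:
    """A planted group-B difference.

    ``target='power'``: state-conditional variance on ``channels`` is
    multiplied by ``multiplier`` (amplitude scaled by sqrt(multiplier)).
    ``target='coherence'``: coupling strength on ``edges`` is shifted
    additively by ``multiplier`` (clipped to [0, 1]).
    ``target='occupancy'``: the state's self-transition is raised,
    ``p_stay' = p_stay + multiplier * (1 - p_stay)`` with ``multiplier`` in
    (0, 1), so the state is occupied longer in group B.
    """
    target: str
    state_id: int
    channels: tuple = ()
    edges: tuple = ()
    multiplier: float = 1.0

    def __post_init__(self):
        if self.target not in ("power", "coherence", "occupancy"):
            raise ValueError(f"unknown effect target {self.target!r}")


@dataclass
class CohortSpec:
    n_per_group: int
    n_channels: int
    fs: float
    duration: float
    transition_matrix: np.ndarray
    state_specs: list
    group_effects: list = field(default_factory=list)
    subject_amp_sd: float = 0.15  # lognormal sd of per-subject amplitude
    seed: int = 0

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        K = self.transition_matrix.shape[0]
        if self.transition_matrix.shape != (K, K):
            raise ValueError("transition matrix must be square")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0,
                           atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.duration * self.fs < 10 * K:
            raise ValueError("duration x fs must be >= 10 x K")
        if len(self.state_specs) != K:
            raise ValueError("need one StateSpec per transition-matrix row")
        for spec in self.state_specs:
            spec.validate(self.fs, self.n_channels)
        ids = {s.state_id for s in self.state_specs}
        for eff in self.group_effects:
            if eff.state_id not in ids:
                raise ValueError(
                    f"effect targets unknown state {eff.state_id}")
            for c in eff.channels:
                if not 0 <= c < self.n_channels:
                    raise ValueError(f"effect channel {c} out of range")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def to_json(self) -> str:
        d = asdict(self)
        d["transition_matrix"] = self.transition_matrix.tolist()
        return json.dumps(d, default=str)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery testing."""
    state_paths: dict          # subject_id -> int array (1..K)
    applied_flips: dict        # subject_id -> per-channel +-1 array
    effect_manifest: list      # realized GroupEffects

    def fractional_occupancy(self, subject_id: str, K: int) -> np.ndarray:
        path = np.asarray(self.state_paths[subject_id])
        return np.bincount(path - 1, minlength=K) / path.size


def simulate_state_path(transition_matrix: np.ndarray, T: int,
                        seed: int | np.random.Generator,
                        initial_distribution: np.ndarray | None = None
                        ) -> np.ndarray:
    """Draw a length-``T`` path (values ``1..K``) from a first-order Markov
    chain.  The initial state is uniform unless a distribution is given."""
    A = np.asarray(transition_matrix, float)
    K = A.shape[0]
    if A.shape != (K, K) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-8) \
            or np.any(A < -1e-12):
        raise ValueError("transition matrix rows must be a simplex")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cdf = np.cumsum(A, axis=1)
    path = np.empty(T, dtype=np.int64)
    if initial_distribution is None:
        state = int(rng.integers(K))
    else:
        state = int(np.searchsorted(np.cumsum(initial_distribution),
                                    rng.random()))
    path[0] = state
    u = rng.random(T - 1)
    for t in range(1, T):
        state = int(np.searchsorted(cdf[state], u[t - 1], side="right"))
        state = min(state, K - 1)  # guard FP edge at u ~ 1
        path[t] = state
    return path + 1


def _segment_runs(path: np.ndarray):
    """Yield (start, stop, state) for maximal constant runs of ``path``."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [path.size]))
    for a, b in zip(starts, stops):
        yield int(a), int(b), int(path[a])


def simulate_subject(state_path: np.ndarray, specs: list, fs: float,
                     seed: int | np.random.Generator,
                     subject_id: str = "s0", group: str | None = None,
                     amp_scale: float = 1.0) -> SubjectTimeSeries:
    """Render one subject from a state path.

    Each maximal run of a state draws fresh oscillator phases; within the
    run every channel receives the loading-weighted sum of that state's
    oscillators, coupled pairs are phase-tied, and white Gaussian noise of
    the state's ``noise_sd`` is added.
    """
    path = np.asarray(state_path)
    by_id = {s.state_id: s for s in specs}
    missing = set(np.unique(path)) - set(by_id)
    if missing:
        raise ValueError(f"no StateSpec for state ids {sorted(missing)}")
    n_channels = None
    for s in by_id.values():
        for osc in s.oscillators:
            n = len(osc.loadings)
            if n_channels is None:
                n_channels = n
            elif n != n_channels:
                raise ValueError("inconsistent loading lengths")
        if 2 * max((o.frequency for o in s.oscillators), default=0.0) >= fs:
            raise ValueError(
                f"fs={fs} aliases state {s.state_id} oscillators")
    if n_channels is None:
        raise ValueError("at least one state must carry an oscillator")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    T = path.size
    X = np.zeros((n_channels, T))
    for a, b, sid in _segment_runs(path):
        spec = by_id[sid]
        n = b - a
        t = np.arange(n) / fs
        seg = np.zeros((n_channels, n))
        shifted = {}  # channel -> oscillation advanced by phase lag cache
        osc_signals = []
        for osc in spec.oscillators:
            phi = rng.uniform(0.0, 2.0 * np.pi)
            theta = 2.0 * np.pi * osc.frequency * t + phi
            L = osc.loading_array(n_channels)
            osc_signals.append((osc, theta, L))
            seg += amp_scale * osc.amplitude * np.outer(L, np.sin(theta))
        for cp in spec.coupled_pairs:
            # oscillation channel i receives, advanced by the phase lag
            y_shift = np.zeros(n)
            for osc, theta, L in osc_signals:
                y_shift += (amp_scale * osc.amplitude * L[cp.i]
                            * np.sin(theta + cp.phase_lag))
            seg[cp.j] = (1.0 - cp.strength) * seg[cp.j] + cp.strength * y_shift
        if spec.noise_sd > 0:
            seg += rng.normal(0.0, spec.noise_sd, size=seg.shape)
        X[:, a:b] = seg
    return SubjectTimeSeries(data=X, fs=fs, subject_id=subject_id,
                             group=group)


def _apply_power_effect(specs: list, eff: GroupEffect) -> list:
    out = []
    amp_mult = float(np.sqrt(eff.multiplier))
    for s in specs:
        if s.state_id != eff.state_id:
            out.append(s)
            continue
        oscs = []
        for osc in s.oscillators:
            load = np.asarray(osc.loadings, float).copy()
            for c in eff.channels:
                load[c] *= amp_mult
            oscs.append(Oscillator(osc.frequency, osc.amplitude,
                                   tuple(load)))
        out.append(StateSpec(s.state_id, tuple(oscs), s.coupled_pairs,
                             s.noise_sd, s.pure_noise))
    return out


def _apply_coherence_effect(specs: list, eff: GroupEffect) -> list:
    out = []
    targets = {tuple(e) for e in eff.edges}
    for s in specs:
        if s.state_id != eff.state_id:
            out.append(s)
            continue
        pairs = []
        seen = set()
        for cp in s.coupled_pairs:
            if (cp.i, cp.j) in targets or (cp.j, cp.i) in targets:
                seen.add((cp.i, cp.j))
                pairs.append(CoupledPair(
                    cp.i, cp.j, cp.phase_lag,
                    float(np.clip(cp.strength + eff.multiplier, 0.0, 1.0))))
            else:
                pairs.append(cp)
        unknown = targets - seen - {(j, i) for i, j in seen}
        if unknown:
            raise ValueError(
                f"coherence effect targets edges {sorted(unknown)} that are "
                f"not coupled pairs of state {eff.state_id}")
        out.append(StateSpec(s.state_id, s.oscillators, tuple(pairs),
                             s.noise_sd, s.pure_noise))
    return out


def _apply_occupancy_effect(A: np.ndarray, eff: GroupEffect,
                            state_ids: list) -> np.ndarray:
    A = A.copy()
    k = state_ids.index(eff.state_id)
    p_stay = A[k, k]
    new_stay = p_stay + eff.multiplier * (1.0 - p_stay)
    off = A[k].copy()
    off[k] = 0.0
    if off.sum() > 0:
        off *= (1.0 - new_stay) / off.sum()
    A[k] = off
    A[k, k] = new_stay
    return A


def simulate_cohort(spec: CohortSpec):
    """Generate a labelled two-group cohort.

    Group A subjects are drawn from ``spec`` as given; group B subjects have
    every ``group_effects`` entry applied.  Per-subject substreams are
    spawned from ``(spec.seed, subject_index)`` so individual subjects are
    reproducible regardless of cohort size.

    Returns ``(subjects, ground_truth)``.
    """
    T = int(round(spec.duration * spec.fs))
    K = spec.n_states
    state_ids = [s.state_id for s in spec.state_specs]

    specs_b = list(spec.state_specs)
    A_b = spec.transition_matrix
    for eff in spec.group_effects:
        if eff.target == "power":
            specs_b = _apply_power_effect(specs_b, eff)
        elif eff.target == "coherence":
            specs_b = _apply_coherence_effect(specs_b, eff)
        elif eff.target == "occupancy":
            A_b = _apply_occupancy_effect(A_b, eff, state_ids)

    subjects, paths, flips = [], {}, {}
    idx = 0
    for group, specs_g, A_g in (("A", spec.state_specs,
                                 spec.transition_matrix),
                                ("B", specs_b, A_b)):
        for _ in range(spec.n_per_group):
            ss = np.random.SeedSequence(entropy=spec.seed,
                                        spawn_key=(idx,))
            rng = np.random.default_rng(ss)
            sid = f"sub{idx:03d}"
            path = simulate_state_path(A_g, T, rng)
            amp = float(np.exp(rng.normal(0.0, spec.subject_amp_sd))) \
                if spec.subject_amp_sd > 0 else 1.0
            ts = simulate_subject(path, specs_g, spec.fs, rng,
                                  subject_id=sid, group=group,
                                  amp_scale=amp)
            subjects.append(ts)
            paths[sid] = path
            flips[sid] = np.ones(spec.n_channels, dtype=np.int64)
            idx += 1
    gt = GroundTruth(state_paths=paths, applied_flips=flips,
                     effect_manifest=list(spec.group_effects))
    return subjects, gt


def corrupt_signs(subjects: list, flip_prob: float,
                  seed: int):
    """Multiply each subject x channel by an i.i.d. +-1 (P(flip)=flip_prob).

    Emulates the arbitrary polarity of source-reconstructed channels.
    Returns ``(new_subjects, applied_flips)`` so recovery can be scored.
    """
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out, applied = [], {}
    for ts in subjects:
        signs = np.where(rng.random(ts.n_channels) < flip_prob, -1.0, 1.0)
        new = ts.copy()
        new.data *= signs[:, None]
        out.append(new)
        applied[ts.subject_id] = signs.astype(np.int64)
    return out, applied


def default_cohort_spec(n_per_group: int = 3, n_channels: int = 12,
                        fs: float = 250.0, duration: float = 120.0,
                        persistence: float = 0.98,
                        frequencies=(5.0, 10.0, 20.0, 35.0),
                        noise_sd: float = 0.2,
                        background_amplitude: float = 0.3,
                        subject_amp_sd: float = 0.15,
                        group_effects: list | None = None,
                        seed: int = 0) -> CohortSpec:
    """Reference synthetic cohort used throughout the tests and docs.

    K states, one per entry of ``frequencies`` (defaults hit the delta/theta,
    alpha, beta and low-gamma bands).  Every channel carries its own
    independent-phase oscillation at its "home" frequency at all times
    (states modulate ongoing rhythms rather than switching them on and
    off, as resting-state networks do): channel ``c`` belongs to state
    ``c // 3``, oscillates at amplitude 1 while its home state is active
    and at ``background_amplitude`` otherwise.  Within its home state the
    second channel of each triplet is phase-coupled to the first at a
    90 degree lag; the third stays uncoupled so coupled and uncoupled
    pairs can be contrasted.  Self-transition ``persistence`` gives mean
    dwell times of ``1/((1-persistence)*fs)`` seconds.
    """
    K = len(frequencies)
    if n_channels < 3 * K:
        raise ValueError("need at least 3 channels per state")
    A = np.full((K, K), (1.0 - persistence) / (K - 1)) if K > 1 \
        else np.ones((1, 1))
    if K > 1:
        np.fill_diagonal(A, persistence)
    specs = []
    for k, f in enumerate(frequencies):
        oscs = []
        for c in range(n_channels):
            home = c // 3
            if home >= K:
                continue  # spare channels carry noise only
            load = np.zeros(n_channels)
            load[c] = 1.0
            amp = 1.0 if home == k else background_amplitude
            if amp > 0:
                oscs.append(Oscillator(frequency=frequencies[home],
                                       amplitude=amp,
                                       loadings=tuple(load)))
        cp = CoupledPair(i=3 * k, j=3 * k + 1, phase_lag=np.pi / 2,
                         strength=1.0)
        specs.append(StateSpec(state_id=k + 1, oscillators=tuple(oscs),
                               coupled_pairs=(cp,), noise_sd=noise_sd))
    return CohortSpec(n_per_group=n_per_group, n_channels=n_channels,
                      fs=fs, duration=duration, transition_matrix=A,
                      state_specs=specs,
                      group_effects=group_effects or [],
                      subject_amp_sd=subject_amp_sd, seed=seed)
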