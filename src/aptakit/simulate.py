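"""Synthetic Cell-SELEX pools and binding curves with known ground truth.

The simulator emulates the statistical structure the analysis assumes:
a large random background plus a handful of true binders that are
exponentially enriched round over round by selection against a
counter-selected background, sequenced to finite depth with substitution
errors.  It is an assumed model — PCR bias, indel errors and realistic
quality profiles are deliberately absent — but it is exactly what makes
every pipeline stage testable end to end with known truth.

Each round applies a deterministic expectation update to the pool's
frequency vector:

1. counter-selection removes the fraction of each species' mass equal
   to its off-target capture probability (background uses the baseline
   ``background_capture``);
2. positive selection multiplies the surviving mass by the capture
   probability on injured cells: ``target_affinity`` for a binder,
   ``background_capture * stringency_schedule[round]`` for background;
3. the vector is renormalized.

Sampling noise enters only when a pool is sequenced
(:func:`emit_pool_fastq`): reads are multinomial draws at the requested
depth, wrapped in the library's constant regions, with per-base
substitution errors.  All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .binding import BindingCurve, one_site
from .library import DEFAULT_LIBRARY, LibraryDesign

__all__ = [
    "BinderSpec",
    "SimConfig",
    "PoolFrequencies",
    "default_config",
    "simulate_initial_library",
    "simulate_selex_round",
    "simulate_arm",
    "emit_pool_fastq",
    "write_ground_truth",
    "simulate_binding_curve",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class BinderSpec:
    """A true binder: its insert and its capture probabilities.

    ``target_affinity`` is the per-round capture probability on injured
    cells; ``offtarget_affinity`` the capture probability on normal
    cells during counter-selection.  A true binder must bind the target
    better than it binds normal cells.
    """

    insert_sequence: str
    target_affinity: float
    offtarget_affinity: float

    def __post_init__(self) -> None:
        if not 0 < self.target_affinity <= 1:
            raise ValueError("target_affinity must be in (0, 1]")
        if not 0 <= self.offtarget_affinity < 1:
            raise ValueError("offtarget_affinity must be in [0, 1)")
        if self.target_affinity <= self.offtarget_affinity:
            raise ValueError("a true binder needs target_affinity > offtarget_affinity")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated selection.

    Defaults model a reduced-diversity version of a Cell-SELEX campaign:
    10^4 distinct background 36-mers (the real library's ~10^15 diversity
    collapses to far fewer distinct survivors after the first rounds),
    5 shared true binders, 8 rounds, 10^5 reads per sequenced pool.
    ``stringency_schedule`` multiplies the background capture rate per
    round, decaying geometrically 1.0 -> 0.2 to emulate the wet-lab
    tightening (5x more normal cells, 5x fewer injured cells, longer
    washes).  ``seq_error_rate`` is a typical per-base substitution rate.
    """

    n_background: int = 10_000
    binders: tuple[BinderSpec, ...] = ()
    rounds: int = 8
    reads_per_round: int = 100_000
    background_capture: float = 0.1
    stringency_schedule: tuple[float, ...] | None = None
    seq_error_rate: float = 0.001
    seed: int = 0
    library: LibraryDesign = DEFAULT_LIBRARY

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0 < self.background_capture <= 1:
            raise ValueError("background_capture must be in (0, 1]")
        if not 0 <= self.seq_error_rate < 1:
            raise ValueError("seq_error_rate must be in [0, 1)")
        if self.stringency_schedule is not None:
            if len(self.stringency_schedule) != self.rounds:
                raise ValueError("stringency_schedule must have one entry per round")
            if any(not 0 < s <= 1 for s in self.stringency_schedule):
                raise ValueError("stringency multipliers must be in (0, 1]")

    @property
    def schedule(self) -> tuple[float, ...]:
        if self.stringency_schedule is not None:
            return self.stringency_schedule
        if self.rounds == 1:
            return (1.0,)
        return tuple(np.geomspace(1.0, 0.2, self.rounds))


@dataclass
class PoolFrequencies:
    """A pool as a frequency distribution over distinct inserts."""

    sequences: list[str]
    freqs: np.ndarray
    is_binder: np.ndarray  # bool mask aligned with sequences

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.is_binder = np.asarray(self.is_binder, dtype=bool)
        if not (len(self.sequences) == self.freqs.size == self.is_binder.size):
            raise ValueError("sequences, freqs and is_binder must align")

    def normalized(self) -> "PoolFrequencies":
        total = self.freqs.sum()
        if total <= 0:
            raise ValueError("zero total mass")
        return PoolFrequencies(self.sequences, self.freqs / total, self.is_binder)


def _random_inserts(rng: np.random.Generator, n: int, length: int,
                    exclude: set[str]) -> list[str]:
    out: list[str] = []
    seen = set(exclude)
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            seq = _BASES[row].tobytes().decode()
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
    return out


def default_config(seed: int, rng: np.random.Generator | None = None,
                   n_binders: int = 5, **overrides) -> SimConfig:
    """A ready-to-run configuration with randomly drawn binder inserts.

    Binder affinities are spread over 0.5–0.9 on target with 0.02
    off-target, comfortably above the 0.1 background capture — the
    regime in which real selections visibly enrich within a few rounds.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([seed, 0xB1]))
    length = overrides.get("library", DEFAULT_LIBRARY).random_length
    inserts = _random_inserts(rng, n_binders, length, exclude=set())
    affinities = np.linspace(0.5, 0.9, n_binders) if n_binders > 1 else [0.7]
    binders = tuple(
        BinderSpec(insert_sequence=s, target_affinity=float(a), offtarget_affinity=0.02)
        for s, a in zip(inserts, affinities)
    )
    return SimConfig(binders=binders, seed=seed, **overrides)


def simulate_initial_library(config: SimConfig) -> PoolFrequencies:
    """Round-0 pool: uniform frequencies over ``n_background`` random
    36-mers plus the configured binders."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x11B]))
    binder_seqs = [b.insert_sequence for b in config.binders]
    background = _random_inserts(
        rng, config.n_background, config.library.random_length, set(binder_seqs)
    )
    sequences = binder_seqs + background
    n = len(sequences)
    return PoolFrequencies(
        sequences=sequences,
        freqs=np.full(n, 1.0 / n),
        is_binder=np.array([True] * len(binder_seqs) + [False] * len(background)),
    )


def _capture_vectors(pool: PoolFrequencies, config: SimConfig,
                     round_index: int) -> tuple[np.ndarray, np.ndarray]:
    offtarget = np.full(len(pool.sequences), config.background_capture)
    capture = np.full(
        len(pool.sequences), config.background_capture * config.schedule[round_index]
    )
    by_seq = {b.insert_sequence: b for b in config.binders}
    for idx, seq in enumerate(pool.sequences):
        b = by_seq.get(seq)
        if b is not None:
            offtarget[idx] = b.offtarget_affinity
            capture[idx] = b.target_affinity
    return offtarget, capture


def simulate_selex_round(
    pool: PoolFrequencies, config: SimConfig, round_index: int
) -> PoolFrequencies:
    """One deterministic selection round (counter-selection, positive
    selection, renormalization).

    In expectation a binder's frequency changes per round by the factor
    target_affinity*(1-offtarget_affinity) / <weighted mean capture>,
    which is > 1 whenever its affinities dominate the background's.
    """
    if not 0 <= round_index < config.rounds:
        raise ValueError("round_index out of range")
    offtarget, capture = _capture_vectors(pool, config, round_index)
    mass = pool.freqs * (1.0 - offtarget) * capture
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero total mass after selection")
    return PoolFrequencies(pool.sequences, mass / total, pool.is_binder)


def simulate_arm(
    config: SimConfig, keep_rounds: tuple[int, ...] | None = None
) -> dict[int, PoolFrequencies]:
    """Run all rounds of one selection arm.

    Returns the pool after each round in ``keep_rounds`` (1-based round
    numbers; round 0 is the initial library).  Defaults to keeping every
    round.
    """
    keep = set(keep_rounds) if keep_rounds is not None else set(range(config.rounds + 1))
    pool = simulate_initial_library(config)
    out: dict[int, PoolFrequencies] = {}
    if 0 in keep:
        out[0] = pool
    for r in range(config.rounds):
        pool = simulate_selex_round(pool, config, r)
        if r + 1 in keep:
            out[r + 1] = pool
    return out


def emit_pool_fastq(
    pool: PoolFrequencies,
    config: SimConfig,
    round_index: int,
    path: str | Path,
    arm: str = "arm",
) -> int:
    """Sequence a pool: multinomial draws at ``reads_per_round`` depth,
    constant regions re-attached, substitution errors applied.

    Deterministic for a fixed (config, seed, round, arm); returns the
    number of reads written.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xF0, round_index, _arm_key(arm)])
    )
    depth = config.reads_per_round
    counts = rng.multinomial(depth, pool.freqs / pool.freqs.sum())
    lib = config.library
    full = [lib.forward_constant + s + lib.reverse_constant for s in pool.sequences]
    mat = np.frombuffer("".join(full).encode(), dtype=np.uint8).reshape(
        len(full), lib.read_length
    )
    idx = np.repeat(np.arange(len(full)), counts)
    rng.shuffle(idx)
    reads = mat[idx].copy()
    if config.seq_error_rate > 0 and reads.size:
        err = rng.random(reads.shape) < config.seq_error_rate
        n_err = int(err.sum())
        if n_err:
            # substitute with one of the three other bases, uniformly
            base_idx = np.searchsorted(_BASES, reads[err])
            shift = rng.integers(1, 4, size=n_err)
            reads[err] = _BASES[(base_idx + shift) % 4]
    qual = "I" * lib.read_length
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for i, row in enumerate(reads):
            handle.write(
                f"@{arm}_r{round_index}_{i}\n{row.tobytes().decode()}\n+\n{qual}\n"
            )
    return int(reads.shape[0])


def _arm_key(arm: str) -> int:
    return sum(ord(c) * 31**k for k, c in enumerate(arm)) % (2**31)


def write_ground_truth(config: SimConfig, path: str | Path) -> None:
    """TSV of the spiked binders (sequence, affinities) for harnesses."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("sequence\ttarget_affinity\tofftarget_affinity\n")
        for b in config.binders:
            handle.write(
                f"{b.insert_sequence}\t{b.target_affinity}\t{b.offtarget_affinity}\n"
            )


def simulate_binding_curve(
    kd_nM: float,
    bmax: float,
    concentrations=None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> BindingCurve:
    """Binding curves from the one-site model, optionally with additive
    Gaussian noise per replicate; noise_sd=0 gives exact model values."""
    if kd_nM <= 0 or bmax <= 0:
        raise ValueError("kd_nM and bmax must be positive")
    from .binding import ASSAY_CONCENTRATIONS_NM

    x = np.asarray(
        ASSAY_CONCENTRATIONS_NM if concentrations is None else concentrations,
        dtype=float,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBD]))
    y = np.tile(one_site(x, bmax, kd_nM), (n_replicates, 1))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return BindingCurve(
        concentrations=x,
        mfi_sample=y,
        mfi_control=np.zeros_like(y),
        label=f"sim_kd{kd_nM:g}",
    )
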