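"""Sequence-based nucleosome occupancy prediction.

The model scores every dyad position with a sequence energy built from the
two determinants the nucleosome-positioning literature agrees on:

* a rotational term rewarding AA/TT/TA/AT dinucleotides placed in phase
  with the helical repeat around the dyad (and GC-set dinucleotides in
  anti-phase), and
* a penalty for poly(dA:dT) tract bases under the 147-bp footprint, since
  long homopolymeric dA:dT stretches resist wrapping.

Energies feed an exact one-dimensional hard-rod (lattice-gas) equilibrium:
nucleosomes are non-overlapping rods of length F with Boltzmann start
weights exp(mu - E(i)), and start/occupancy probabilities come from
partition-function recursions (log domain throughout).  The chemical
potential mu is either given or calibrated by bisection to a target mean
coverage.

This is a re-implementation in spirit of published occupancy predictors,
not a clone of any particular one; parameter defaults are conventional and
exposed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
from scipy import stats as _stats

from . import _lattice
from .composition_features import AT_DINUCS, GC_DINUCS, _DINUC_INDEX, _dinuc_codes, find_polyAT_mask
from .sequence_io import SequenceRecord


class InfeasibleCoverageError(ValueError):
    """Target coverage exceeds the maximum packing fraction."""


class UndefinedCorrelationError(ValueError):
    """Pearson/Spearman similarity of a constant track is undefined."""


@dataclass(frozen=True)
class NucleosomeModelParams:
    """Tunable parameters of the occupancy model.

    footprint        rod length F in bp (odd, so the dyad is a base)
    period           helical repeat P in bp for the rotational term
    amplitude        lambda, kT reward per perfectly in-phase dinucleotide
    polyAT_penalty   gamma, kT per poly(dA:dT) tract base under the footprint
    tract_min        minimum homopolymer run length counted as a tract
    mu               chemical potential in kT; None -> calibrate
    target_coverage  mean occupancy used to calibrate mu when mu is None
    """

    footprint: int = 147
    period: float = 10.1
    amplitude: float = 0.05
    polyAT_penalty: float = 0.02
    tract_min: int = 5
    mu: Optional[float] = None
    target_coverage: float = 0.75

    def __post_init__(self) -> None:
        if self.footprint < 3 or self.footprint % 2 == 0:
            raise ValueError("footprint must be odd and >= 3")
        if self.period <= 2:
            raise ValueError("period must exceed 2 bp")
        if self.amplitude < 0 or self.polyAT_penalty < 0:
            raise ValueError("amplitude and polyAT_penalty must be >= 0")
        if not (0 <= self.target_coverage < 1):
            raise ValueError("target_coverage must lie in [0, 1)")


@dataclass
class EnergyProfile:
    """Per-start dyad binding energy E(i) in kT.

    ``energies[i]`` is the energy of a footprint starting at base i; the
    dyad sits at i + (F-1)/2.  Linear profiles have L - F + 1 entries,
    circular ones L.
    """

    energies: np.ndarray
    footprint: int
    topology: str
    seq_id: str = ""

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")

    @property
    def n_starts(self) -> int:
        return len(self.energies)

    @property
    def seq_length(self) -> int:
        if self.topology == "circular":
            return len(self.energies)
        return len(self.energies) + self.footprint - 1

    def dyad_positions(self) -> np.ndarray:
        return np.arange(self.n_starts) + (self.footprint - 1) // 2


@dataclass
class OccupancyProfile:
    """Equilibrium start probabilities and per-base occupancy."""

    start_prob: np.ndarray
    occupancy: np.ndarray
    footprint: int
    topology: str
    mu: float
    seq_id: str = ""

    def __post_init__(self) -> None:
        self.start_prob = np.asarray(self.start_prob, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        # conservation: o(j) = sum of s over covering starts, so occupancy
        # must never stray outside [0, 1] beyond round-off
        if self.start_prob.size and (self.occupancy.max(initial=0) > 1 + 1e-9
                                     or self.occupancy.min(initial=0) < -1e-12):
            raise ValueError("occupancy outside [0, 1]")

    @property
    def mean_occupancy(self) -> float:
        return float(self.occupancy.mean())


def _energy_from_codes(pair: np.ndarray, polyat_mask: np.ndarray,
                       params: NucleosomeModelParams, circular: bool) -> np.ndarray:
    """E(i) from dinucleotide codes and a poly(dA:dT) base mask."""
    F, P = params.footprint, params.period
    half = (F - 1) // 2
    # dinucleotide start offsets j = 0..F-2; the helical phase is referenced
    # to the dinucleotide center (j + 0.5), which makes the energy exactly
    # symmetric under reverse complement
    j = np.arange(F - 1)
    kernel = np.cos(2 * np.pi * (j + 0.5 - half) / P)
    at_idx = np.array([_DINUC_INDEX[d] for d in AT_DINUCS])
    gc_idx = np.array([_DINUC_INDEX[d] for d in GC_DINUCS])
    signal = np.isin(pair, at_idx).astype(float) - np.isin(pair, gc_idx).astype(float)
    mask = polyat_mask.astype(float)
    if circular:
        L = len(mask)
        sig_ext = np.concatenate([signal, signal[:F - 2]]) if F > 2 else signal
        mask_ext = np.concatenate([mask, mask[:F - 1]])
        periodic = np.correlate(sig_ext, kernel, mode="valid")[:L]
        tract = np.correlate(mask_ext, np.ones(F), mode="valid")[:L]
    else:
        periodic = np.correlate(signal, kernel, mode="valid")
        tract = np.correlate(mask, np.ones(F), mode="valid")
    return -params.amplitude * periodic + params.polyAT_penalty * tract


def dyad_energy(rec: SequenceRecord, params: NucleosomeModelParams = NucleosomeModelParams()) -> EnergyProfile:
    """Sequence energy per footprint start position.

    E(i) = -lambda * sum_j cos(2 pi j'/P) [d_j in AT-set] - (same, negated,
    for the GC set) + gamma * (# footprint bases inside poly(dA:dT) tracts
    of length >= tract_min), with j' the offset of dinucleotide j from the
    dyad.
    """
    L = len(rec)
    circular = rec.is_circular
    if not circular and L < params.footprint:
        raise IndexError(f"sequence length {L} shorter than footprint {params.footprint}")
    pair = _dinuc_codes(rec.sequence, circular)
    mask = find_polyAT_mask(rec, min_len=params.tract_min)
    energies = _energy_from_codes(pair, mask, params, circular)
    return EnergyProfile(energies=energies, footprint=params.footprint,
                         topology=rec.topology, seq_id=rec.id)


def occupancy(E: EnergyProfile, params: NucleosomeModelParams = NucleosomeModelParams(),
              mu: Optional[float] = None) -> OccupancyProfile:
    """Exact hard-rod equilibrium occupancy for the given energies.

    mu resolution order: explicit argument, then params.mu, then
    calibration to params.target_coverage.
    """
    if mu is None:
        mu = params.mu
    if mu is None:
        mu = calibrate_mu(E, params.target_coverage)
    F = E.footprint
    circular = E.topology == "circular"
    logw = mu - E.energies if np.isfinite(mu) else np.full(E.n_starts, -np.inf)
    if circular:
        s, _ = _lattice.circular_stats(logw, F)
    else:
        s, _ = _lattice.linear_stats(logw, F)
    o = _lattice.coverage_from_starts(s, F, circular)
    o = np.clip(o, 0.0, 1.0)
    return OccupancyProfile(start_prob=s, occupancy=o, footprint=F,
                            topology=E.topology, mu=float(mu), seq_id=E.seq_id)


def _mean_occ(E: EnergyProfile, F: int, circular: bool, mu: float) -> float:
    logw = mu - E.energies
    if circular:
        s, _ = _lattice.circular_stats(logw, F)
    else:
        s, _ = _lattice.linear_stats(logw, F)
    return float(_lattice.coverage_from_starts(s, F, circular).mean())


def max_packing_fraction(E: EnergyProfile) -> float:
    """Coverage attained by the densest rod packing on this lattice."""
    F = E.footprint
    L = E.seq_length
    return F * (L // F) / L


def calibrate_mu(E: EnergyProfile, target_coverage: float, tol: float = 1e-4,
                 max_iter: int = 200) -> float:
    """Chemical potential achieving the target mean occupancy, by bisection.

    Mean occupancy is non-decreasing in mu, so bisection converges; a
    target of 0 returns -inf (empty lattice).  Targets at or above the
    maximum packing fraction are infeasible.
    """
    if not (0 <= target_coverage < 1):
        raise ValueError("target_coverage must lie in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if target_coverage == 0:
        return -math.inf
    if target_coverage >= max_packing_fraction(E) - 1e-12:
        raise InfeasibleCoverageError(
            f"coverage {target_coverage} unreachable; max packing "
            f"{max_packing_fraction(E):.4f}"
        )
    F = E.footprint
    circular = E.topology == "circular"
    scale = float(np.median(E.energies))
    lo, hi = scale - 30.0, scale + 30.0
    for _ in range(60):
        if _mean_occ(E, F, circular, lo) < target_coverage:
            break
        lo -= 30.0
    for _ in range(60):
        if _mean_occ(E, F, circular, hi) > target_coverage:
            break
        hi += 30.0
    else:
        raise InfeasibleCoverageError("could not bracket the target coverage")
    mu = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mu = 0.5 * (lo + hi)
        m = _mean_occ(E, F, circular, mu)
        if abs(m - target_coverage) <= tol:
            return mu
        if m < target_coverage:
            lo = mu
        else:
            hi = mu
    return mu


def predict(rec: SequenceRecord, params: NucleosomeModelParams = NucleosomeModelParams()) -> OccupancyProfile:
    """dyad_energy -> (calibrate_mu) -> occupancy, in one call."""
    E = dyad_energy(rec, params)
    return occupancy(E, params)


def find_peaks(track: np.ndarray, circular: bool = False) -> np.ndarray:
    """Strict local maxima of a track; plateau peaks report their midpoint."""
    x = np.asarray(track, dtype=float)
    n = len(x)
    if n < 3:
        return np.array([], dtype=int)
    peaks = []

    def val(k):
        return x[k % n] if circular else x[k]

    i = 0
    while i < n:
        if not circular and (i == 0 or i == n - 1):
            i += 1
            continue
        j = i
        while j + 1 < (n if circular else n) and val(j + 1) == val(i):
            j += 1
        left = val(i - 1) if (circular or i > 0) else -np.inf
        if j >= n - 1 and not circular:
            break
        right = val(j + 1)
        if val(i) > left and val(i) > right:
            peaks.append((i + j) // 2)
        i = j + 1
    return np.array(sorted(set(peaks)), dtype=int)


def _as_track(obj) -> np.ndarray:
    if isinstance(obj, OccupancyProfile):
        return obj.occupancy
    return np.asarray(obj, dtype=float)


def profile_similarity(a, b, method: str = "pearson", peak_dist: int = 20) -> float:
    """Similarity of two occupancy tracks.

    Tracks of unequal length are linearly resampled onto the shorter
    track's 1-bp grid.  ``pearson``/``spearman`` correlate the
    mean-centred tracks; ``peak_match`` is the fraction of peaks of ``a``
    matched by a peak of ``b`` within ``peak_dist`` bp.
    """
    xa, xb = _as_track(a), _as_track(b)
    if len(xa) != len(xb):
        n = min(len(xa), len(xb))
        grid = np.linspace(0, 1, n)
        xa = np.interp(grid, np.linspace(0, 1, len(xa)), xa)
        xb = np.interp(grid, np.linspace(0, 1, len(xb)), xb)
    if method in ("pearson", "spearman"):
        if np.std(xa) == 0 or np.std(xb) == 0:
            raise UndefinedCorrelationError("correlation of a constant track is undefined")
        if method == "pearson":
            return float(_stats.pearsonr(xa - xa.mean(), xb - xb.mean())[0])
        return float(_stats.spearmanr(xa, xb)[0])
    if method == "peak_match":
        pa, pb = find_peaks(xa), find_peaks(xb)
        if len(pa) == 0:
            return float("nan")
        if len(pb) == 0:
            return 0.0
        hits = sum(1 for p in pa if np.min(np.abs(pb - p)) <= peak_dist)
        return hits / len(pa)
    raise ValueError(f"unknown method {method!r}")
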