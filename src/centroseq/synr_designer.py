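"""Constrained sequence randomization (SynR design).

Scrambles a sequence in small fixed windows — each window replaced by a
random permutation of its own bases, so base composition is conserved
exactly — then anneals single-window re-shuffles until the candidate

* has diverged enough from the original (identity <= max_identity),
* keeps the genome-wide dinucleotide spectrum (L1 distance <= tol), and
* keeps the predicted nucleosome occupancy profile (Pearson r >= min_occ_r,
  both profiles computed at the chemical potential calibrated once on the
  original).

Positions inside single-base (homopolymer) windows can never change, which
puts a floor on the reachable identity; an infeasible identity cap is
reported as a diagnostic, not an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nucleosome_model as nm
from .composition_features import DINUCLEOTIDES, find_polyAT_mask
from .nucleosome_model import NucleosomeModelParams
from .sequence_io import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _to_codes(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("designer requires an unambiguous A/C/G/T sequence")
    return arr.astype(np.uint8)


def _to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass(frozen=True)
class DesignConstraints:
    """Contract for an acceptable randomized sequence."""

    window: int = 5
    stride: Optional[int] = None  # None -> non-overlapping (= window)
    max_identity: float = 0.75
    dinuc_l1_tol: float = 0.02
    min_occ_r: float = 0.8
    preserve_tracts: bool = True
    max_iter: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not (0 <= self.max_identity <= 1):
            raise ValueError("max_identity must lie in [0, 1]")
        if self.dinuc_l1_tol < 0 or self.max_iter < 0:
            raise ValueError("tolerances and max_iter must be >= 0")


@dataclass
class DesignResult:
    """A candidate sequence and its divergence/conservation metrics."""

    sequence: SequenceRecord
    identity: float
    at_delta: float
    dinuc_l1: float
    occ_r: float
    tract_jaccard: float
    iterations: int
    accepted: bool
    seed: int
    diagnostic: Optional[str] = None


def window_shuffle(rec: SequenceRecord, window: int = 5,
                   stride: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None) -> SequenceRecord:
    """Permute each window's bases independently; composition-conserving.

    Windows are laid at ``stride`` (default = window, non-overlapping) and
    applied left to right.  A trailing window shorter than ``window`` is
    still shuffled when it has at least 2 bases.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    L = len(rec)
    if L < window:
        raise ValueError("sequence shorter than the shuffle window")
    rng = np.random.default_rng() if rng is None else rng
    stride = window if stride is None else stride
    codes = _to_codes(rec.sequence).copy()
    if stride == window:
        n_win = L // window
        body = codes[: n_win * window].reshape(n_win, window)
        order = np.argsort(rng.random((n_win, window)), axis=1)
        codes[: n_win * window] = np.take_along_axis(body, order, axis=1).ravel()
        tail = L - n_win * window
        if tail >= 2:
            codes[n_win * window:] = rng.permutation(codes[n_win * window:])
    else:
        for start in range(0, L, stride):
            chunk = codes[start:start + window]
            if len(chunk) >= 2:
                codes[start:start + len(chunk)] = rng.permutation(chunk)
    return SequenceRecord(id=f"{rec.id}_shuffled", sequence=_to_seq(codes),
                          topology=rec.topology)


def identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Gapless position-wise identity of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    xa = np.frombuffer(a.sequence.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.sequence.encode(), dtype=np.uint8)
    return float((xa == xb).mean())


def homopolymer_identity_floor(rec: SequenceRecord, window: int = 5,
                               stride: Optional[int] = None) -> float:
    """Fraction of positions inside single-base windows: no within-window
    permutation can change them, bounding identity from below."""
    stride = window if stride is None else stride
    codes = _to_codes(rec.sequence)
    L = len(rec)
    fixed = 0
    for start in range(0, L, stride):
        chunk = codes[start:start + window]
        if len(chunk) == 0:
            break
        if len(chunk) == 1 or (chunk == chunk[0]).all():
            fixed += len(chunk)
        if stride == window and start + window >= L:
            break
    return fixed / L


def _dinuc_freqs_codes(codes: np.ndarray) -> np.ndarray:
    pair = codes[:-1].astype(np.int64) * 4 + codes[1:]
    counts = np.bincount(pair, minlength=16).astype(float)
    return counts / counts.sum()


def _tract_positions(rec: SequenceRecord, min_len: int) -> frozenset:
    from .composition_features import find_at_tracts
    pos = set()
    for tr in find_at_tracts(rec, min_len=min_len, mode="mixed_AT"):
        pos.update(range(tr.region.start, tr.region.start + tr.length))
    return frozenset(pos)


def evaluate_design(original: SequenceRecord, candidate: SequenceRecord,
                    model_params: NucleosomeModelParams = NucleosomeModelParams(),
                    mu: Optional[float] = None) -> dict:
    """Divergence/conservation metrics of a candidate vs its original.

    Occupancy correlation uses one chemical potential for both profiles:
    the one calibrated on the original at the model's target coverage
    (passed in as ``mu`` to avoid recalibration), so differences in occ_r
    reflect sequence, not normalization.
    """
    if len(original) != len(candidate):
        raise ValueError("original and candidate must have equal lengths")
    from .composition_features import at_content
    if mu is None:
        mu = nm.calibrate_mu(nm.dyad_energy(original, model_params),
                             model_params.target_coverage)
    occ_o = nm.occupancy(nm.dyad_energy(original, model_params), model_params, mu=mu)
    occ_c = nm.occupancy(nm.dyad_energy(candidate, model_params), model_params, mu=mu)
    ta, tb = (_tract_positions(original, model_params.tract_min),
              _tract_positions(candidate, model_params.tract_min))
    union = ta | tb
    jac = len(ta & tb) / len(union) if union else 1.0
    fo = _dinuc_freqs_codes(_to_codes(original.sequence))
    fc = _dinuc_freqs_codes(_to_codes(candidate.sequence))
    return {
        "identity": identity(original, candidate),
        "at_delta": abs(at_content(original) - at_content(candidate)),
        "dinuc_l1": float(np.abs(fo - fc).sum()),
        "occ_r": nm.profile_similarity(occ_o, occ_c, method="pearson"),
        "tract_jaccard": jac,
        "mu": mu,
    }


def _penalty(metrics: dict, c: DesignConstraints) -> float:
    return (max(0.0, c.min_occ_r - metrics["occ_r"])
            + max(0.0, metrics["dinuc_l1"] - c.dinuc_l1_tol)
            + max(0.0, metrics["identity"] - c.max_identity))


def design_synr(original: SequenceRecord,
                constraints: DesignConstraints = DesignConstraints(),
                model_params: NucleosomeModelParams = NucleosomeModelParams()) -> DesignResult:
    """Anneal window re-shuffles until all design constraints hold.

    The initial candidate is a full window_shuffle of the original; each
    proposal re-permutes one randomly chosen window and is accepted by
    simulated annealing (T0 = 1, geometric cooling 0.995/iteration) on the
    summed constraint violations.  Composition is conserved exactly at
    every step.  The run is fully reproducible from the seed; failure to
    satisfy the constraints within max_iter returns the best candidate
    with ``accepted=False``.
    """
    c = constraints
    w = c.window
    if len(original) < w:
        raise ValueError("sequence shorter than the design window")
    rng = np.random.default_rng(c.seed)
    orig_codes = _to_codes(original.sequence)
    L = len(original)

    mu = nm.calibrate_mu(nm.dyad_energy(original, model_params),
                         model_params.target_coverage)
    occ_orig = nm.occupancy(nm.dyad_energy(original, model_params),
                            model_params, mu=mu).occupancy

    floor = homopolymer_identity_floor(original, w, c.stride)
    diagnostic = None
    if c.max_identity < floor:
        diagnostic = (
            f"identity cap {c.max_identity:.3f} is below the homopolymer "
            f"floor {floor:.3f}: positions inside single-base windows cannot change"
        )

    stride = w if c.stride is None else c.stride
    starts = np.arange(0, L - 1, stride)

    def metrics_of(codes: np.ndarray) -> dict:
        cand = SequenceRecord(id="cand", sequence=_to_seq(codes),
                              topology=original.topology)
        E = nm.dyad_energy(cand, model_params)
        occ = nm.occupancy(E, model_params, mu=mu).occupancy
        if np.std(occ) == 0 or np.std(occ_orig) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(occ_orig, occ)[0, 1])
        fo = _dinuc_freqs_codes(orig_codes)
        fc = _dinuc_freqs_codes(codes)
        return {
            "identity": float((codes == orig_codes).mean()),
            "dinuc_l1": float(np.abs(fo - fc).sum()),
            "occ_r": r,
        }

    codes = _to_codes(
        window_shuffle(original, w, c.stride, rng).sequence
    )
    met = metrics_of(codes)
    pen = _penalty(met, c)
    best_codes, best_pen = codes.copy(), pen

    T = 1.0
    cooling = 0.995
    iterations = 0
    if diagnostic is None:
        for iterations in range(1, c.max_iter + 1):
            if pen <= 0:
                break
            start = int(starts[rng.integers(len(starts))])
            chunk = codes[start:start + w]
            prop = codes.copy()
            prop[start:start + len(chunk)] = rng.permutation(chunk)
            met_p = metrics_of(prop)
            pen_p = _penalty(met_p, c)
            if pen_p <= pen or rng.random() < math.exp(-(pen_p - pen) / T):
                codes, met, pen = prop, met_p, pen_p
                if pen < best_pen:
                    best_codes, best_pen = codes.copy(), pen
            T *= cooling
        if pen > best_pen:
            codes, pen = best_codes, best_pen
            met = metrics_of(codes)

    accepted = diagnostic is None and pen <= 0
    candidate = SequenceRecord(id=f"{original.id}_synr", sequence=_to_seq(codes),
                               topology=original.topology)
    full = evaluate_design(original, candidate, model_params, mu=mu)
    assert full["at_delta"] == 0.0, "within-window permutation must conserve composition"
    if not accepted and diagnostic is None:
        diagnostic = (
            f"constraints not satisfied after {iterations} iterations "
            f"(residual penalty {pen:.4f})"
        )
    return DesignResult(
        sequence=candidate,
        identity=full["identity"],
        at_delta=full["at_delta"],
        dinuc_l1=full["dinuc_l1"],
        occ_r=full["occ_r"],
        tract_jaccard=full["tract_jaccard"],
        iterations=iterations,
        accepted=accepted,
        seed=c.seed,
        diagnostic=diagnostic,
    )
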