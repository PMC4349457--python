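"""Sequence-composition features of centromeric DNA.

Central-domain DNA of fission-yeast centromeres is AT-rich (~72% versus a
~64% genome average), carries long poly(dA:dT) tracts, and shows ~10-bp
periodic placement of flexible AA/TT/TA/AT dinucleotides — the rotational
signal that phases DNA on the nucleosome.  This module quantifies those
properties: global and windowed AT content, dinucleotide frequencies, a
periodicity spectrum of a chosen dinucleotide set, and maximal
poly(dA:dT)-tract calls.

N bases are excluded from composition denominators and break tracts and
dinucleotides.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .sequence_io import Region, SequenceRecord, reverse_complement

#: Rotational-signal dinucleotides favouring bendability toward the histone
#: octamer (minor groove in), the conventional AT set.
AT_DINUCS = frozenset({"AA", "TT", "TA", "AT"})
#: Complementary rigid/GC set (minor groove out).
GC_DINUCS = frozenset({"GG", "CC", "GC", "CG"})

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

_TRACT_PATTERNS = {
    "homopolymer_A": "A",
    "homopolymer_T": "T",
    "mixed_AT": "[AT]",
}


class UndefinedContentError(ValueError):
    """Composition is undefined (e.g. an all-N sequence)."""


class FlatSpectrumWarning(UserWarning):
    """The periodicity indicator carries no signal; the peak is undefined."""


@dataclass
class CompositionProfile:
    """Windowed AT-content track: AT fraction per window center."""

    positions: np.ndarray
    values: np.ndarray
    window: int
    step: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.values = np.asarray(self.values, dtype=float)
        assert len(self.positions) == len(self.values)


@dataclass
class PeriodicitySpectrum:
    """Periodicity score of a dinucleotide indicator on a period (bp) grid.

    ``power`` is the combined periodicity score whose argmax defines
    ``peak_period``; the two evidence tracks it is built from — the Hann
    periodogram and the footprint-limited autocorrelation comb — are kept
    in ``fourier_power`` and ``comb_score`` for inspection.
    """

    periods: np.ndarray
    power: np.ndarray
    peak_period: float
    dinuc_set: frozenset
    fourier_power: Optional[np.ndarray] = None
    comb_score: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.periods = np.asarray(self.periods, dtype=float)
        self.power = np.asarray(self.power, dtype=float)


@dataclass(frozen=True)
class ATTract:
    """A maximal run of A, T, or A/T bases of at least the configured length."""

    region: Region
    mode: str
    length: int


def at_content(rec: SequenceRecord) -> float:
    """Fraction (#A + #T) / (#A + #C + #G + #T); N excluded from both sides."""
    s = rec.sequence
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    denom = a + c + g + t
    if denom == 0:
        raise UndefinedContentError(f"{rec.id!r}: no unambiguous bases")
    return (a + t) / denom


def at_percent(rec: SequenceRecord) -> int:
    """AT content as an integer percent, rounded half-up (e.g. 72)."""
    import math
    return int(math.floor(at_content(rec) * 100 + 0.5))


def windowed_at(rec: SequenceRecord, window: int, step: int = 1) -> CompositionProfile:
    """Sliding-window AT fraction.  Circular sequences wrap so every start
    position yields a window; windows containing only N are NaN."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    L = len(rec)
    if window > L and not rec.is_circular:
        raise IndexError(f"window {window} exceeds linear sequence length {L}")
    arr = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
    is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(float)
    is_base = (arr != ord("N")).astype(float)
    if rec.is_circular:
        pad = window - 1
        is_at = np.concatenate([is_at, is_at[:pad]])
        is_base = np.concatenate([is_base, is_base[:pad]])
        starts = np.arange(0, L, step)
    else:
        starts = np.arange(0, L - window + 1, step)
    cum_at = np.concatenate([[0.0], np.cumsum(is_at)])
    cum_b = np.concatenate([[0.0], np.cumsum(is_base)])
    num = cum_at[starts + window] - cum_at[starts]
    den = cum_b[starts + window] - cum_b[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    centers = starts + window // 2
    return CompositionProfile(positions=centers, values=vals, window=window, step=step)


def _dinuc_codes(seq: str, circular: bool) -> np.ndarray:
    """Overlapping-dinucleotide codes 0..15; N-containing pairs are -1."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    if circular:
        first, second = code, np.roll(code, -1)
    else:
        first, second = code[:-1], code[1:]
    pair = first * 4 + second
    pair[(first < 0) | (second < 0)] = -1
    return pair


def dinucleotide_freqs(rec: SequenceRecord) -> Dict[str, float]:
    """Overlapping-dinucleotide frequencies normalized to sum 1.

    Linear sequences contribute L-1 pairs, circular ones L (the wrap pair
    included).  Pairs containing N are dropped before normalization.
    """
    if len(rec) < 2:
        raise IndexError("need at least 2 bases for dinucleotide counts")
    pair = _dinuc_codes(rec.sequence, rec.is_circular)
    valid = pair[pair >= 0]
    counts = np.bincount(valid, minlength=16).astype(float)
    total = counts.sum()
    if total == 0:
        raise UndefinedContentError(f"{rec.id!r}: no unambiguous dinucleotides")
    return {d: counts[i] / total for i, d in enumerate(DINUCLEOTIDES)}


def dinuc_vector(freqs: Dict[str, float]) -> np.ndarray:
    """Frequency dict -> fixed-order 16-vector (A*, C*, G*, T* rows)."""
    return np.array([freqs[d] for d in DINUCLEOTIDES])


def _fourier_power(x: np.ndarray, periods: np.ndarray, hann: bool) -> np.ndarray:
    """Hann periodogram of the centred indicator, interpolated onto the
    period grid (zero-padded FFT for a smooth frequency interpolation)."""
    if hann:
        x = x * np.hanning(len(x))
    n_fft = 1 << max(12, int(np.ceil(np.log2(len(x) * 8))))
    spec = np.abs(np.fft.rfft(x, n=n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft)
    return np.interp(1.0 / periods, freqs, spec)


def _comb_score(x: np.ndarray, periods: np.ndarray, lag_min: float,
                lag_max: float) -> np.ndarray:
    """Matched-filter comb on the autocorrelation, phase-insensitive.

    For each candidate period p the autocorrelation is sampled at the
    multiples of p up to ``lag_max`` (each tooth averaged over +/- 1 bp to
    absorb integer-placement jitter), weighted by a triangular coherence
    taper and normalized so that pure noise scores equally at every p.
    Restricting lags to roughly one nucleosome footprint makes the score
    insensitive to phase differences between distant signal patches.
    """
    n = len(x)
    nf = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nf)
    r = np.fft.irfft(f * np.conj(f), nf)[:n] / n
    lags = np.arange(n, dtype=float)
    offsets = np.arange(-1, 2)
    score = np.zeros(len(periods))
    for i, p in enumerate(periods):
        m = np.arange(max(1, int(np.ceil(lag_min / p))), int(lag_max / p) + 1)
        if len(m) == 0:
            continue
        sample = (m[:, None] * p + offsets[None, :]).ravel()
        teeth = np.interp(sample, lags, r).reshape(len(m), 3).mean(axis=1)
        w = 1.0 - (m * p) / (lag_max + p)
        score[i] = float((teeth * w).sum() / np.sqrt((w * w).sum()))
    return score


def periodicity_spectrum(
    rec: SequenceRecord,
    dinuc_set: frozenset = AT_DINUCS,
    min_period: float = 2.0,
    max_period: float = 50.0,
    hann: bool = True,
    n_grid: int = 960,
    lag_min: float = 4.0,
    lag_max: Optional[float] = None,
) -> PeriodicitySpectrum:
    """Estimate the dominant placement periodicity of a dinucleotide set.

    A binary indicator marks positions starting a dinucleotide in
    ``dinuc_set``.  Two independent statistics are computed on the
    mean-centred indicator and combined multiplicatively into the
    periodicity score: the (Hann) periodogram, which is sharp but assumes
    a single coherent phase along the whole sequence, and an
    autocorrelation comb limited to lags of about one nucleosome footprint
    (default ``lag_max`` 150 bp), which tolerates phase changes between
    signal patches — as between adjacent nucleosomes, whose rotational
    signals need not be in register.  ``peak_period`` is the argmax of the
    combined score on the period grid.  A signal-free indicator (all zero
    or all one) yields a flat spectrum, a warning, and ``peak_period =
    nan``.
    """
    L = len(rec)
    if not (2 <= min_period < max_period <= L / 2):
        raise ValueError("need 2 <= min_period < max_period <= length/2")
    pair = _dinuc_codes(rec.sequence, rec.is_circular)
    wanted = np.array([_DINUC_INDEX[d] for d in dinuc_set])
    indicator = np.isin(pair, wanted).astype(float)
    x = indicator - indicator.mean()
    periods = np.linspace(min_period, max_period, n_grid)
    if not np.any(np.abs(x) > 0):
        warnings.warn("dinucleotide indicator has no variation; spectrum is flat",
                      FlatSpectrumWarning)
        return PeriodicitySpectrum(periods=periods, power=np.zeros(n_grid),
                                   peak_period=float("nan"),
                                   dinuc_set=frozenset(dinuc_set))
    if lag_max is None:
        lag_max = float(min(len(x) // 2, 150))
    fourier = _fourier_power(x, periods, hann)
    comb = _comb_score(x, periods, lag_min, lag_max)
    f_max = fourier.max()
    c_max = comb.max()
    if f_max <= 0 or c_max <= 0:
        warnings.warn("no periodic signal detected; spectrum is flat",
                      FlatSpectrumWarning)
        return PeriodicitySpectrum(periods=periods, power=np.zeros(n_grid),
                                   peak_period=float("nan"),
                                   dinuc_set=frozenset(dinuc_set),
                                   fourier_power=fourier, comb_score=comb)
    power = (fourier / f_max) * (np.maximum(comb, 0.0) / c_max)
    peak = float(periods[int(np.argmax(power))])
    return PeriodicitySpectrum(periods=periods, power=power, peak_period=peak,
                               dinuc_set=frozenset(dinuc_set),
                               fourier_power=fourier, comb_score=comb)


def find_at_tracts(rec: SequenceRecord, min_len: int = 5,
                   mode: str = "mixed_AT") -> List[ATTract]:
    """Maximal A/T tracts of at least ``min_len`` bases, sorted by start.

    ``homopolymer_A``/``homopolymer_T`` report single-base runs;
    ``mixed_AT`` reports runs over {A,T}.  On circular sequences a run may
    span the origin (reported with start > end).  N breaks every tract.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if mode not in _TRACT_PATTERNS:
        raise ValueError(f"unknown tract mode {mode!r}")
    charset = _TRACT_PATTERNS[mode]
    L = len(rec)
    seq = rec.sequence
    tracts: List[ATTract] = []
    if rec.is_circular and re.fullmatch(f"{charset}+", seq):
        region = Region(rec.id, 0, L, ".", label=f"{mode}_tract")
        return [ATTract(region=region, mode=mode, length=L)]
    scan = seq + seq[: L - 1] if rec.is_circular else seq
    pattern = re.compile(f"{charset}{{{min_len},}}")
    for m in pattern.finditer(scan):
        start, end = m.start(), m.end()
        if start >= L:
            continue
        if rec.is_circular and start == 0 and seq[-1:] and re.fullmatch(charset, seq[-1]):
            # run continues across the origin; the wrapped copy reports it
            continue
        length = min(end - start, L)
        region = Region(rec.id, start, (start + length) % L if rec.is_circular and start + length > L else start + length,
                        ".", label=f"{mode}_tract")
        tracts.append(ATTract(region=region, mode=mode, length=length))
    return tracts


def find_polyAT_mask(rec: SequenceRecord, min_len: int = 5) -> np.ndarray:
    """Boolean per-base mask of poly(dA:dT) bases: positions inside maximal
    homopolymer A-runs or T-runs of length >= min_len."""
    mask = np.zeros(len(rec), dtype=bool)
    for mode in ("homopolymer_A", "homopolymer_T"):
        for tr in find_at_tracts(rec, min_len=min_len, mode=mode):
            r = tr.region
            if r.start < r.end:
                mask[r.start:r.end] = True
            else:  # origin-spanning
                mask[r.start:] = True
                mask[:r.end] = True
    return mask


def revcomp_dinuc_permutation() -> Dict[str, str]:
    """Dinucleotide -> its reverse complement (the permutation under which
    the frequency vector of a reverse-complemented sequence maps back)."""
    return {d: reverse_complement(d) for d in DINUCLEOTIDES}
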