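"""Synthetic inputs with the statistical structure of centromeric data.

Generates, deterministically from a seed:

* genome-like i.i.d. background at a chosen AT fraction (default 64%, the
  S. pombe genome average),
* 2-kb central-domain-like sequences at 72% AT carrying planted
  poly(dA:dT) tracts and an in-phase AA/TT dinucleotide signal around
  chosen dyad positions (helical period 10.1 bp), returned together with
  the ground truth needed to score recovery,
* noisy occupancy tracks, and
* replicate qPCR Ct tables with Gaussian noise on the cycle scale
  (log-scale multiplicative on abundance, the usual qPCR error structure).

Defaults describe a realistic central-domain fragment: 12 homopolymer
tracts of 5-15 bp over 2 kb and 9 dyads at ~200-bp spacing (nucleosomal
repeat length), with the rotational signal written at every cosine maximum
inside the 147-bp footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nucleosome_model import OccupancyProfile
from .sequence_io import Region, SequenceRecord


@dataclass
class CentromereSimSpec:
    """Parameters of a simulated central-domain-like sequence."""

    length: int = 2000
    at_target: float = 0.72
    background_at: float = 0.64
    n_tracts: int = 12
    tract_len_range: Tuple[int, int] = (5, 15)
    planted_dyads: Optional[Sequence[int]] = None  # None -> 200-bp ladder
    period: float = 10.1
    footprint: int = 147
    signal_density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.at_target < 1 and 0 < self.background_at < 1):
            raise ValueError("AT fractions must lie in (0, 1)")
        if self.tract_len_range[0] < 2 or self.tract_len_range[0] > self.tract_len_range[1]:
            raise ValueError("bad tract length range")
        half = self.footprint // 2
        if self.planted_dyads is None:
            self.planted_dyads = list(range(150, self.length - half, 200))
        for d in self.planted_dyads:
            if d < half or d > self.length - 1 - half:
                raise ValueError(f"dyad {d} too close to a sequence end")


def gen_background(length: int, at_fraction: float = 0.64,
                   seed: int = 0, id: str = "background") -> SequenceRecord:
    """I.i.d. sequence with P(A)=P(T)=at/2 and P(C)=P(G)=(1-at)/2."""
    if not (0 < at_fraction <= 1):
        raise ValueError("at_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    p = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    codes = rng.choice(4, size=length, p=p)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
    return SequenceRecord(id=id, sequence=seq, topology="linear")


def gen_central_domain_like(spec: CentromereSimSpec) -> Tuple[SequenceRecord, Dict]:
    """Centromere-like sequence plus ground truth of its planted features.

    Background is drawn at ``at_target``; homopolymer A or T tracts are
    written over it at non-overlapping positions clear of the planted
    dyads' footprints; AA or TT dinucleotides are written at every cosine
    maximum of the helical phase inside each dyad's footprint (thinned by
    ``signal_density``).  Truth lists tract Regions and dyad positions.
    """
    rng = np.random.default_rng(spec.seed)
    rec = gen_background(spec.length, spec.at_target, seed=int(rng.integers(2**31)),
                         id="central_domain_like")
    codes = np.frombuffer(rec.sequence.encode(), dtype=np.uint8).copy()
    L = spec.length
    half = spec.footprint // 2

    # keep-out zone: planted dyad footprints (so tracts never overwrite the
    # rotational signal, and vice versa)
    blocked = np.zeros(L, dtype=bool)
    for d in spec.planted_dyads:
        blocked[max(0, d - half):d + half + 1] = True

    tracts: List[Region] = []
    attempts = 0
    while len(tracts) < spec.n_tracts:
        attempts += 1
        if attempts > 2000 * max(1, spec.n_tracts):
            raise ValueError("could not place the requested tracts without overlap")
        tl = int(rng.integers(spec.tract_len_range[0], spec.tract_len_range[1] + 1))
        start = int(rng.integers(0, L - tl + 1))
        # one spacer base on each side keeps planted tracts maximal/separate
        lo, hi = max(0, start - 1), min(L, start + tl + 1)
        if blocked[lo:hi].any():
            continue
        base = ord("A") if rng.random() < 0.5 else ord("T")
        codes[start:start + tl] = base
        # non-A/T flanks keep the planted tract maximal (in homopolymer and
        # mixed modes alike) at exactly its recorded interval
        for flank in (start - 1, start + tl):
            if 0 <= flank < L and codes[flank] in (ord("A"), ord("T")):
                codes[flank] = ord("G") if rng.random() < 0.5 else ord("C")
        blocked[lo:hi] = True
        tracts.append(Region("central_domain_like", start, start + tl, ".",
                             label="planted_tract"))
    tracts.sort(key=lambda r: r.start)

    n_phases = int(half // spec.period)
    signal = np.zeros(L, dtype=bool)
    for d in spec.planted_dyads:
        for k in range(-n_phases, n_phases + 1):
            if spec.signal_density < 1.0 and rng.random() > spec.signal_density:
                continue
            pos = d + int(round(k * spec.period))
            if pos < 0 or pos + 1 >= L:
                continue
            pair = b"AA" if rng.random() < 0.5 else b"TT"
            codes[pos], codes[pos + 1] = pair[0], pair[1]
            signal[pos:pos + 2] = True

    # planted features skew composition AT-ward; rebalance background
    # positions so the realized AT count hits the target exactly.  Flips are
    # spread uniformly (only the features themselves and tract flanks are
    # protected) so the background stays homogeneous.
    protected = signal.copy()
    for r in tracts:
        protected[max(0, r.start - 1):min(L, r.end + 1)] = True
    is_at = (codes == ord("A")) | (codes == ord("T"))
    free = ~protected
    target_count = int(round(spec.at_target * L))
    excess = int(is_at.sum()) - target_count
    if excess > 0:
        pool = np.flatnonzero(free & is_at)
    else:
        pool = np.flatnonzero(free & ~is_at)
    if abs(excess) > len(pool):
        raise ValueError("planted features leave too few free bases to reach at_target")
    flip = rng.choice(pool, size=abs(excess), replace=False)
    if excess > 0:
        codes[flip] = np.where(rng.random(len(flip)) < 0.5, ord("G"), ord("C"))
    else:
        codes[flip] = np.where(rng.random(len(flip)) < 0.5, ord("A"), ord("T"))

    out = SequenceRecord(id="central_domain_like",
                         sequence=codes.tobytes().decode(), topology="linear")
    truth = {"tracts": tracts, "dyads": list(spec.planted_dyads),
             "period": spec.period, "spec": spec}
    return out, truth


def gen_occupancy_track(profile: OccupancyProfile | np.ndarray,
                        noise_sd: float = 0.05, seed: int = 0) -> np.ndarray:
    """Occupancy plus i.i.d. Gaussian noise, clipped to [0, 1]."""
    base = profile.occupancy if isinstance(profile, OccupancyProfile) else np.asarray(profile, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = base + rng.normal(0.0, noise_sd, size=base.shape)
    return np.clip(noisy, 0.0, 1.0)


def gen_qpcr_table(true_percent_ip: Dict[str, float], replicate_sd_ct: float = 0.2,
                   n_reps: int = 3, seed: int = 0, efficiency: float = 2.0,
                   input_fraction: float = 0.01,
                   ct_input_base: float = 20.0) -> pd.DataFrame:
    """Long-format Ct table realizing the given true %IP per target.

    Ct values are back-computed from the percent-of-input formula
    (Ct_IP = Ct_input - log_E(%IP / (100 f))) and jittered with Gaussian
    noise on the cycle scale.  At sd = 0 the %IP computation inverts the
    table exactly.
    """
    if replicate_sd_ct < 0 or n_reps < 1:
        raise ValueError("need replicate_sd_ct >= 0 and n_reps >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    logE = math.log(efficiency)
    for target, pct in true_percent_ip.items():
        if pct <= 0:
            raise ValueError(f"true %IP for {target!r} must be positive")
        delta = math.log(pct / (100.0 * input_fraction)) / logE
        ct_ip_true = ct_input_base - delta
        for rep in range(1, n_reps + 1):
            rows.append({"target": target, "sample": "input", "replicate": rep,
                         "ct": ct_input_base + rng.normal(0, replicate_sd_ct)})
            rows.append({"target": target, "sample": "IP", "replicate": rep,
                         "ct": ct_ip_true + rng.normal(0, replicate_sd_ct)})
    return pd.DataFrame(rows)
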