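"""Occupancy model: energies vs a naive oracle, recursions vs enumeration."""

import math

import numpy as np
import pytest

from centroseq import _lattice
from centroseq.composition_features import AT_DINUCS, GC_DINUCS
from centroseq.nucleosome_model import (
    EnergyProfile,
    InfeasibleCoverageError,
    NucleosomeModelParams,
    UndefinedCorrelationError,
    calibrate_mu,
    dyad_energy,
    find_peaks,
    occupancy,
    predict,
    profile_similarity,
)
from centroseq.sequence_io import SequenceRecord
from centroseq.synthetic_data import CentromereSimSpec, gen_central_domain_like


def naive_dyad_energy(seq, params, circular=False):
    """Independent position-by-position evaluation of the energy formula."""
    F, P = params.footprint, params.period
    L = len(seq)
    half = (F - 1) // 2
    # poly(dA:dT) mask: maximal homopolymer A or T runs of length >= tract_min
    mask = [False] * L
    for base in "AT":
        i = 0
        while i < L:
            if seq[i % L] == base:
                j = i
                while j < i + L and seq[j % L] == base:
                    j += 1
                if j - i >= params.tract_min and not (circular and j - i >= L):
                    for k in range(i, min(j, i + L)):
                        mask[k % L] = True
                elif circular and j - i >= L:
                    for k in range(L):
                        mask[k] = True
                i = j
            else:
                i += 1
        if not circular:
            # redo without wraparound
            mask_lin = [False] * L
            i = 0
            while i < L:
                if seq[i] == base:
                    j = i
                    while j < L and seq[j] == base:
                        j += 1
                    if j - i >= params.tract_min:
                        for k in range(i, j):
                            mask_lin[k] = True
                    i = j
                else:
                    i += 1
            for k in range(L):
                mask[k] = mask[k] or mask_lin[k]
    n_starts = L if circular else L - F + 1
    out = []
    for i in range(n_starts):
        e = 0.0
        for j in range(F - 1):
            d = seq[(i + j) % L] + seq[(i + j + 1) % L]
            c = math.cos(2 * math.pi * (j + 0.5 - half) / params.period)
            if d in AT_DINUCS:
                e -= params.amplitude * c
            elif d in GC_DINUCS:
                e += params.amplitude * c
        tract = sum(1 for j in range(F) if mask[(i + j) % L])
        out.append(e + params.polyAT_penalty * tract)
    return np.array(out)


class TestDyadEnergy:
    def test_zero_for_inert_sequence(self):
        # alternating A/G has no AT-set or GC-set dinucleotide and no tracts
        params = NucleosomeModelParams(footprint=11, tract_min=5)
        E = dyad_energy(SequenceRecord(id="x", sequence="AG" * 30), params)
        assert np.allclose(E.energies, 0.0)

    def test_matches_naive_oracle_linear(self):
        rng = np.random.default_rng(11)
        params = NucleosomeModelParams(footprint=21, period=10.1,
                                       amplitude=0.07, polyAT_penalty=0.03)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), p=[0.36, 0.14, 0.14, 0.36], size=300))
            rec = SequenceRecord(id="r", sequence=seq)
            E = dyad_energy(rec, params)
            assert np.allclose(E.energies, naive_dyad_energy(seq, params), atol=1e-10)

    def test_matches_naive_oracle_circular(self):
        rng = np.random.default_rng(12)
        params = NucleosomeModelParams(footprint=15, amplitude=0.05, polyAT_penalty=0.02)
        seq = "".join(rng.choice(list("ACGT"), p=[0.36, 0.14, 0.14, 0.36], size=120))
        rec = SequenceRecord(id="r", sequence=seq, topology="circular")
        E = dyad_energy(rec, params)
        assert len(E.energies) == 120
        assert np.allclose(E.energies, naive_dyad_energy(seq, params, circular=True),
                           atol=1e-10)

    def test_reverse_complement_symmetry(self):
        # AT and GC sets are each closed under reverse complement, so the
        # energy profile of the reverse complement is the reverse profile
        rng = np.random.default_rng(13)
        params = NucleosomeModelParams(footprint=21)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        fwd = dyad_energy(SequenceRecord(id="f", sequence=seq), params).energies
        from centroseq.sequence_io import reverse_complement
        rev = dyad_energy(SequenceRecord(id="r", sequence=reverse_complement(seq)),
                          params).energies
        assert np.allclose(fwd, rev[::-1], atol=1e-10)

    def test_too_short_linear(self):
        with pytest.raises(IndexError):
            dyad_energy(SequenceRecord(id="x", sequence="ACGT"),
                        NucleosomeModelParams(footprint=147))


class TestOccupancyRecursion:
    @pytest.mark.parametrize("circular", [False, True])
    @pytest.mark.parametrize("F", [2, 3, 4])
    def test_equals_enumeration_small_lattices(self, F, circular):
        rng = np.random.default_rng(100 * F + circular)
        for L in range(F, 13):
            n = L if circular else L - F + 1
            logw = rng.normal(0, 2, size=n)
            if circular:
                s, logZ = _lattice.circular_stats(logw, F)
            else:
                s, logZ = _lattice.linear_stats(logw, F)
            s_ref, logZ_ref = _lattice.enumerate_stats(logw, F, circular)
            assert np.max(np.abs(s - s_ref)) < 1e-9
            assert abs(logZ - logZ_ref) < 1e-9

    def test_uniform_circular_symmetry(self):
        E = EnergyProfile(energies=np.zeros(10), footprint=3, topology="circular")
        occ = occupancy(E, mu=0.5)
        assert np.allclose(occ.start_prob, occ.start_prob[0])
        assert np.allclose(occ.occupancy, occ.occupancy[0])

    def test_empty_lattice_limit(self):
        E = EnergyProfile(energies=np.zeros(8), footprint=3, topology="linear")
        occ = occupancy(E, mu=-100.0)
        assert np.all(occ.occupancy < 1e-30)

    def test_occupancy_is_windowed_sum_of_starts(self):
        rng = np.random.default_rng(2)
        E = EnergyProfile(energies=rng.normal(0, 1, 50), footprint=5, topology="linear")
        occ = occupancy(E, mu=0.0)
        L = 54
        for j in range(L):
            covering = [i for i in range(50) if i <= j < i + 5]
            assert occ.occupancy[j] == pytest.approx(occ.start_prob[covering].sum(),
                                                     abs=1e-12)

    def test_rotational_invariance_circular(self):
        rng = np.random.default_rng(3)
        e = rng.normal(0, 1, 20)
        base = occupancy(EnergyProfile(energies=e, footprint=4, topology="circular"), mu=0.3)
        for k in (1, 5, 13):
            rolled = occupancy(EnergyProfile(energies=np.roll(e, k), footprint=4,
                                             topology="circular"), mu=0.3)
            assert np.allclose(rolled.occupancy, np.roll(base.occupancy, k), atol=1e-10)

    def test_no_overflow_on_long_sequence(self):
        rng = np.random.default_rng(4)
        E = EnergyProfile(energies=rng.normal(0, 1, 10_000), footprint=147,
                          topology="linear")
        occ = occupancy(E, mu=50.0)  # strong adsorption, would overflow linearly
        assert np.isfinite(occ.occupancy).all()
        assert occ.occupancy.max() <= 1.0


class TestCalibrateMu:
    def test_zero_target_returns_neg_inf(self):
        E = EnergyProfile(energies=np.zeros(10), footprint=2, topology="circular")
        mu = calibrate_mu(E, 0.0)
        assert mu == -math.inf
        assert occupancy(E, mu=mu).mean_occupancy <= 1e-12

    def test_uniform_circular_hits_target_vs_enumeration(self):
        E = EnergyProfile(energies=np.zeros(10), footprint=2, topology="circular")
        mu = calibrate_mu(E, 0.5, tol=1e-6)
        s_ref, _ = _lattice.enumerate_stats(np.full(10, mu), 2, True)
        occ_ref = _lattice.coverage_from_starts(s_ref, 2, True)
        assert occ_ref.mean() == pytest.approx(0.5, abs=1e-5)

    def test_mean_occupancy_monotone_in_mu(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            E = EnergyProfile(energies=rng.normal(0, 1, 40), footprint=5,
                              topology="linear")
            means = [occupancy(E, mu=m).mean_occupancy for m in np.linspace(-6, 6, 13)]
            assert np.all(np.diff(means) > -1e-12)

    def test_infeasible_coverage(self):
        E = EnergyProfile(energies=np.zeros(8), footprint=3, topology="linear")
        with pytest.raises(InfeasibleCoverageError):
            calibrate_mu(E, 0.95)  # max packing on L=10 linear with F=3 is 0.9


class TestPredict:
    def test_planted_dyads_are_occupancy_maxima(self):
        hits = total = 0
        for seed in range(5):
            rec, truth = gen_central_domain_like(CentromereSimSpec(seed=seed))
            occ = predict(rec)
            peaks = find_peaks(occ.occupancy)
            for d in truth["dyads"]:
                total += 1
                if peaks.size and np.min(np.abs(peaks - d)) <= 20:
                    hits += 1
        assert hits / total >= 0.8

    def test_mean_occupancy_hits_default_target(self):
        rec, _ = gen_central_domain_like(CentromereSimSpec(seed=1))
        occ = predict(rec)
        assert occ.mean_occupancy == pytest.approx(0.75, abs=1e-3)


class TestProfileSimilarity:
    def test_self_similarity(self):
        rng = np.random.default_rng(0)
        a = rng.random(200)
        assert profile_similarity(a, a) == pytest.approx(1.0)
        assert profile_similarity(a, a, method="peak_match") == 1.0

    def test_anticorrelation(self):
        rng = np.random.default_rng(1)
        a = rng.random(200)
        assert profile_similarity(a, -a) == pytest.approx(-1.0)

    def test_constant_track_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            profile_similarity(np.ones(50), np.arange(50.0))

    def test_noisy_copy_highly_correlated(self):
        x = np.sin(np.linspace(0, 20, 500))
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = x + rng.normal(0, 0.1 * x.std(), size=x.shape)
            assert profile_similarity(x, noisy) > 0.9

    def test_resampling_different_lengths(self):
        x = np.sin(np.linspace(0, 20, 500))
        y = np.sin(np.linspace(0, 20, 250))
        assert profile_similarity(x, y) > 0.99


class TestFindPeaks:
    def test_strict_local_maxima(self):
        track = np.array([0, 1, 0, 2, 0, 3, 0], dtype=float)
        assert list(find_peaks(track)) == [1, 3, 5]

    def test_plateau_midpoint(self):
        track = np.array([0, 1, 1, 1, 0], dtype=float)
        assert list(find_peaks(track)) == [2]

    def test_boundaries_excluded_linear(self):
        track = np.array([5, 1, 0, 1, 5], dtype=float)
        assert list(find_peaks(track)) == []
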