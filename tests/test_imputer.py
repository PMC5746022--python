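import numpy as np
import pytest

from herdimpute.errors import HerdimputeError, MissingSiteError
from herdimpute.evaluate import concordance
from herdimpute.genodata import GenotypeMatrix, PanelDefinition, mask_to_panel
from herdimpute.imputer import (
    HaplotypeLibrary,
    build_library,
    impute,
    phase_matrix,
    two_step_impute,
)

from conftest import make_gm, make_sites


def gm_from_haps(haps, sites=None, prefix="s"):
    """Diploid matrix whose row i is haps[i][0] + haps[i][1]."""
    haps = np.asarray(haps, dtype=np.int8)
    sites = sites or make_sites(haps.shape[2])
    dosage = haps.sum(axis=1)
    return GenotypeMatrix([f"{prefix}{i}" for i in range(len(haps))], sites, dosage)


class TestBuildLibrary:
    def test_homozygous_reference_exact(self):
        haps = np.array([
            [[0, 0, 0, 0], [0, 0, 0, 0]],
            [[1, 1, 1, 1], [1, 1, 1, 1]],
        ])
        lib = build_library(gm_from_haps(haps))
        assert lib.n_haplotypes == 2
        assert lib.counts.tolist() == [2, 2]

    def test_hand_phasable_counts(self):
        # animal 1: H1/H1, animal 2: H1/H2 with one het site -> {H1:3, H2:1}
        h1 = [0, 0, 0, 0]
        h2 = [0, 0, 0, 1]
        haps = np.array([[h1, h1], [h1, h2]])
        lib = build_library(gm_from_haps(haps))
        by_hap = dict(zip(map(tuple, lib.haplotypes), lib.counts))
        assert by_hap == {tuple(h1): 3, tuple(h2): 1}

    def test_single_het_site_two_haplotypes(self):
        gm = make_gm([[1]])
        lib = build_library(gm)
        assert sorted(map(tuple, lib.haplotypes)) == [(0,), (1,)]

    def test_empty_reference_errors(self):
        gm = GenotypeMatrix([], make_sites(3), np.zeros((0, 3), dtype=np.int8))
        with pytest.raises(HerdimputeError):
            build_library(gm)


def make_panel(sites, idx):
    return PanelDefinition("low", tuple(sites[i] for i in idx))


class TestImpute:
    def test_unique_match_is_exact(self, rng):
        # 6 distinct haplotypes over 60 sites, targets homozygous carriers,
        # uniquely identified by every 5th site
        H = rng.integers(0, 2, size=(6, 60)).astype(np.int8)
        while len({tuple(h) for h in H[:, ::5]}) < 6:
            H = rng.integers(0, 2, size=(6, 60)).astype(np.int8)
        sites = make_sites(60)
        lib = HaplotypeLibrary(sites, H, np.full(6, 2))
        pairs = [(0, 1), (2, 3), (4, 5), (1, 4)]
        truth = gm_from_haps(np.array([[H[a], H[b]] for a, b in pairs]), sites)
        low = mask_to_panel(truth, make_panel(sites, range(0, 60, 5)))
        out = impute(low, lib)
        recs = concordance(out, truth)
        assert all(r.concordance == 1.0 for r in recs)

    def test_zero_observed_loci_modal_fill(self):
        sites = make_sites(10)
        H = np.array([[0] * 10, [1] * 10], dtype=np.int8)
        lib = HaplotypeLibrary(sites, H, np.array([5, 1]))
        empty = GenotypeMatrix(
            ["t0"], [], np.zeros((1, 0), dtype=np.int8)
        )
        out = impute(empty, lib)
        assert out.dosage.tolist() == [[0] * 10]  # modal haplotype, twice

    def test_output_complete_and_in_library_order(self, rng):
        H = rng.integers(0, 2, size=(4, 30)).astype(np.int8)
        sites = make_sites(30)
        lib = HaplotypeLibrary(sites, H, np.full(4, 1))
        truth = gm_from_haps(np.array([[H[0], H[1]]]), sites)
        low = mask_to_panel(truth, make_panel(sites, range(0, 30, 3)))
        out = impute(low, lib)
        assert (out.dosage >= 0).all()
        assert [s.key for s in out.sites] == [s.key for s in sites]

    def test_target_site_missing_from_library(self):
        sites = make_sites(5)
        lib = HaplotypeLibrary(sites[:4], np.zeros((1, 4), dtype=np.int8), np.array([1]))
        tgt = make_gm([[0, 0, 0, 0, 0]])
        with pytest.raises(MissingSiteError):
            impute(tgt, lib)

    def test_observed_genotypes_preserved(self, rng):
        H = rng.integers(0, 2, size=(4, 40)).astype(np.int8)
        sites = make_sites(40)
        lib = HaplotypeLibrary(sites, H, np.full(4, 1))
        # target inconsistent with every library pair at some observed loci
        tgt_dosage = rng.integers(0, 3, size=(1, 8)).astype(np.int8)
        obs_sites = [sites[i] for i in range(0, 40, 5)]
        tgt = GenotypeMatrix(["t"], obs_sites, tgt_dosage)
        out = impute(tgt, lib)
        lookup = {s.key: j for j, s in enumerate(out.sites)}
        for j, s in enumerate(obs_sites):
            assert out.dosage[0, lookup[s.key]] == tgt_dosage[0, j]

    def test_single_switch_mosaics(self):
        """Targets recombining two library haplotypes once stay >= 0.98 concordant."""
        concs = []
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            H = rng.integers(0, 2, size=(8, 400)).astype(np.int8)
            sites = make_sites(400)
            lib = HaplotypeLibrary(sites, H, np.full(8, 2))
            a, b = rng.choice(8, size=2, replace=False)
            cut = rng.integers(100, 300)
            mosaic = np.concatenate([H[a, :cut], H[b, cut:]])
            other = H[rng.integers(8)]
            truth = gm_from_haps(np.array([[mosaic, other]]), sites)
            low = mask_to_panel(truth, make_panel(sites, range(0, 400, 4)))
            out = impute(low, lib)
            concs.append(concordance(out, truth)[0].concordance)
        assert np.mean(concs) >= 0.98

    def test_library_enlargement_with_relatives_helps(self):
        """Adding the targets' true haplotypes to the library never hurts on average."""
        deltas = []
        for rep in range(20):
            rng = np.random.default_rng(2000 + rep)
            base = rng.integers(0, 2, size=(10, 200)).astype(np.int8)
            sites = make_sites(200)
            true_pair = rng.integers(0, 2, size=(2, 200)).astype(np.int8)
            truth = gm_from_haps(true_pair[None, :, :], sites)
            low = mask_to_panel(truth, make_panel(sites, range(0, 200, 10)))
            small = HaplotypeLibrary(sites, base, np.full(10, 1))
            big = HaplotypeLibrary(
                sites,
                np.concatenate([base, true_pair]),
                np.full(12, 1),
            )
            c_small = concordance(impute(low, small), truth)[0].concordance
            c_big = concordance(impute(low, big), truth)[0].concordance
            deltas.append(c_big - c_small)
        assert np.mean(deltas) >= 0.0


class TestPhaseMatrix:
    def test_dosage_conserved(self, rng):
        from conftest import random_gm

        gm = random_gm(rng, 20, 50)
        ph = phase_matrix(gm)
        assert (ph.sum(axis=1) == gm.dosage).all()

    def test_deterministic(self, rng):
        from conftest import random_gm

        gm = random_gm(rng, 10, 40)
        assert (phase_matrix(gm) == phase_matrix(gm)).all()


class TestTwoStep:
    def test_two_step_runs_and_improves_over_modal(self, rng):
        H = rng.integers(0, 2, size=(6, 120)).astype(np.int8)
        sites = make_sites(120)
        ref = gm_from_haps(
            np.array([[H[i], H[i]] for i in range(6)]), sites, prefix="r"
        )
        truth = gm_from_haps(np.array([[H[0], H[3]]]), sites, prefix="t")
        low = mask_to_panel(truth, make_panel(sites, range(0, 120, 12)))
        mid_sites = [sites[i] for i in range(0, 120, 3)]
        out = two_step_impute(low, ref, mid_sites)
        assert concordance(out, truth)[0].concordance == 1.0
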