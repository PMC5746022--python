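import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herdimpute.errors import (
    DuplicateSiteError,
    FormatError,
    MissingSiteError,
)
from herdimpute.genodata import (
    MISSING,
    GenotypeMatrix,
    PanelDefinition,
    Pedigree,
    Site,
    filter_min_allele_count,
    mask_to_panel,
    read_genotypes_tsv,
    read_pedigree_tsv,
    read_plink_text,
    read_vcf,
    write_genotypes,
)

from conftest import make_gm, make_sites


VCF_3x2 = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\t.\tC\tT\t.\t.\t.\tGT\t1|1\t0|0\t0/1
"""


def write(tmp_path, text, name="in.vcf"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestReadVcf:
    def test_dosage_transcription(self, tmp_path):
        gm = read_vcf(write(tmp_path, VCF_3x2))
        assert gm.sample_ids == ["a", "b", "c"]
        assert [s.key for s in gm.sites] == [("1", 100), ("1", 200)]
        assert gm.dosage.tolist() == [[0, 2], [1, 0], [2, 1]]

    def test_missing_genotype(self, tmp_path):
        vcf = VCF_3x2.replace("0/0\t0/1\t1/1", "./.\t0/1\t1/1")
        gm = read_vcf(write(tmp_path, vcf))
        assert gm.dosage[0, 0] == MISSING

    def test_multiallelic_rejected_by_default(self, tmp_path):
        vcf = VCF_3x2.replace("1\t200\t.\tC\tT", "1\t200\t.\tC\tT,G")
        with pytest.raises(FormatError):
            read_vcf(write(tmp_path, vcf))
        gm = read_vcf(write(tmp_path, vcf), drop_multiallelic=True)
        assert gm.n_sites == 1

    def test_duplicate_site_error(self, tmp_path):
        vcf = VCF_3x2.replace("1\t200", "1\t100")
        with pytest.raises(DuplicateSiteError):
            read_vcf(write(tmp_path, vcf))

    def test_sites_sorted_by_position(self, tmp_path):
        lines = VCF_3x2.splitlines()
        swapped = "\n".join(lines[:4] + [lines[5], lines[4]]) + "\n"
        gm = read_vcf(write(tmp_path, swapped))
        assert [s.pos for s in gm.sites] == [100, 200]


class TestReadPlinkText:
    def test_allele_pairs(self, tmp_path):
        mp = write(tmp_path, "1 snp1 100 A G\n1 snp2 200 C T\n", "m.map")
        gp = write(tmp_path, "x A A C T\ny A G T T\nz 0 0 C C\n", "g.txt")
        gm = read_plink_text(mp, gp)
        assert gm.dosage.tolist() == [[0, 1], [1, 2], [MISSING, 0]]

    def test_dosage_table(self, tmp_path):
        mp = write(tmp_path, "1 snp1 100\n1 snp2 200\n", "m.map")
        gp = write(tmp_path, "x 0 2\ny 1 NA\n", "g.txt")
        gm = read_plink_text(mp, gp)
        assert gm.dosage.tolist() == [[0, 2], [1, MISSING]]

    def test_count_mismatch_is_format_error(self, tmp_path):
        mp = write(tmp_path, "1 snp1 100\n1 snp2 200\n", "m.map")
        gp = write(tmp_path, "x 0 2 1\n", "g.txt")
        with pytest.raises(FormatError):
            read_plink_text(mp, gp)


class TestMaskToPanel:
    def test_identity(self):
        gm = make_gm([[0, 1, 2], [2, 1, 0]])
        panel = PanelDefinition("p", tuple(gm.sites))
        out = mask_to_panel(gm, panel)
        assert out.dosage.tolist() == gm.dosage.tolist()

    def test_subset_preserves_dosage(self):
        gm = make_gm(np.arange(20).reshape(2, 10) % 3)
        keep = [gm.sites[i] for i in (1, 4, 8)]
        out = mask_to_panel(gm, PanelDefinition("p", tuple(keep)))
        assert [s.pos for s in out.sites] == [keep[0].pos, keep[1].pos, keep[2].pos]
        assert out.dosage.tolist() == gm.dosage[:, [1, 4, 8]].tolist()

    def test_absent_site_raises(self):
        gm = make_gm([[0, 1], [1, 2]])
        bad = PanelDefinition("p", (Site(chrom="1", pos=99999),))
        with pytest.raises(MissingSiteError):
            mask_to_panel(gm, bad)

    def test_nested_masking_composes(self, rng):
        from conftest import random_gm

        gm = random_gm(rng, 5, 12)
        outer = PanelDefinition("o", tuple(gm.sites[i] for i in range(0, 12, 2)))
        inner = PanelDefinition("i", tuple(gm.sites[i] for i in (0, 4, 8)))
        assert inner.is_subset_of(outer)
        via = mask_to_panel(mask_to_panel(gm, outer), inner)
        direct = mask_to_panel(gm, inner)
        assert via.dosage.tolist() == direct.dosage.tolist()


class TestMinAlleleCountFilter:
    def test_boundary_below_and_at_threshold(self):
        # site 0: minor allele count 3 (removed); site 1: exactly 4 (kept)
        d = np.zeros((10, 2), dtype=np.int8)
        d[0, 0] = 2
        d[1, 0] = 1
        d[:4, 1] = 1
        gm = make_gm(d)
        out, removed = filter_min_allele_count(gm, min_count=4)
        assert [s.pos for s in removed] == [gm.sites[0].pos]
        assert out.n_sites == 1 and out.sites[0].pos == gm.sites[1].pos

    def test_monomorphic_removed(self):
        gm = make_gm(np.zeros((5, 3), dtype=np.int8))
        out, removed = filter_min_allele_count(gm)
        assert out.n_sites == 0 and len(removed) == 3

    def test_minor_allele_is_frequency_based_not_alt(self):
        # ALT is the major allele here: 9 animals hom-alt, one het.
        d = np.full((10, 1), 2, dtype=np.int8)
        d[0, 0] = 1
        gm = make_gm(d)
        out, _ = filter_min_allele_count(gm, min_count=4)
        assert out.n_sites == 0  # minor (ref) allele count is 1 < 4

    def test_idempotent(self, rng):
        from conftest import random_gm

        gm = random_gm(rng, 20, 30, missing_rate=0.05)
        once, _ = filter_min_allele_count(gm)
        twice, removed2 = filter_min_allele_count(once)
        assert removed2 == []
        assert twice.dosage.tolist() == once.dosage.tolist()


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["vcf", "tsv"])
    def test_small_matrix(self, tmp_path, fmt):
        gm = make_gm([[0, 1, MISSING], [2, 1, 0]])
        path = str(tmp_path / f"out.{fmt}")
        write_genotypes(gm, path, fmt)
        back = read_vcf(path) if fmt == "vcf" else read_genotypes_tsv(path)
        assert back.sample_ids == gm.sample_ids
        assert [s.key for s in back.sites] == [s.key for s in gm.sites]
        assert back.dosage.tolist() == gm.dosage.tolist()

    def test_empty_matrix_header_only(self, tmp_path):
        gm = GenotypeMatrix(["a", "b"], [], np.zeros((2, 0), dtype=np.int8))
        path = str(tmp_path / "empty.vcf")
        write_genotypes(gm, path, "vcf")
        back = read_vcf(path)
        assert back.sample_ids == ["a", "b"] and back.n_sites == 0

    @settings(max_examples=20, deadline=None)
    @given(st.data())
    def test_random_matrices(self, tmp_path_factory, data):
        n = data.draw(st.integers(1, 6))
        m = data.draw(st.integers(1, 8))
        entries = data.draw(
            st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=n * m, max_size=n * m)
        )
        gm = make_gm(np.array(entries, dtype=np.int8).reshape(n, m))
        tmp = tmp_path_factory.mktemp("rt")
        for fmt, reader in (("vcf", read_vcf), ("tsv", read_genotypes_tsv)):
            path = str(tmp / f"f.{fmt}")
            write_genotypes(gm, path, fmt)
            back = reader(path)
            assert back.dosage.tolist() == gm.dosage.tolist()


class TestPedigree:
    def test_cycle_detection(self):
        with pytest.raises(FormatError):
            Pedigree({"a": ("b", None), "b": ("a", None)})

    def test_round_trip_and_unknown_parents(self, tmp_path):
        p = tmp_path / "ped.tsv"
        p.write_text("id\tsire\tdam\nx\t0\t0\ny\tx\t0\n")
        ped = read_pedigree_tsv(str(p))
        assert ped.parents_of("y") == ["x"]
        assert ped.parents_of("x") == []
        assert ped.progeny_of("x") == ["y"]
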