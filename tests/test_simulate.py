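"""Simulator: determinants are planted as specified, outputs are
deterministic, and everything round-trips through the standard formats."""

import numpy as np
import pytest
from scipy import stats

from svcontext import io as svio
from svcontext.dataset import SVRecord
from svcontext.errors import ConfigurationError
from svcontext.simulate import (GroundTruthManifest, SimulationConfig,
                                generate_reference, load_fixture,
                                simulate_fixture, simulate_small_variants,
                                simulate_svs, write_fixture)


def small_config(**kw):
    base = dict(seed=3, n_chromosomes=1, chrom_length=60_000,
                n_sv_per_class={"te_insertion": 10, "deletion_mh": 10,
                                "simple_repeat": 5, "inversion": 5},
                n_genes=30)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateReference:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=20_000,
                               gc_by_chrom=[0.5], seed=42, n_genes=10)
        a, _ = generate_reference(cfg)
        b, _ = generate_reference(cfg)
        assert a.sequences() == b.sequences()

    def test_gc_tracks_target(self):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=100_000,
                               gc_by_chrom=[0.30], seed=5, n_genes=10)
        ref, _ = generate_reference(cfg)
        s = str(ref["chr1"])
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.28 <= gc <= 0.32
        assert set(s) <= set("ACGT")

    def test_chromosome_count_and_annotations(self):
        ref, ann = generate_reference(small_config(n_chromosomes=3,
                                                   chrom_length=60_000))
        assert sorted(ref.keys()) == ["chr1", "chr2", "chr3"]
        for key in ("simple_repeat", "alu", "l1"):
            assert sum(len(ann[key].intervals(c)) for c in ref.keys()) > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(chrom_length=100)
        with pytest.raises(ConfigurationError):
            SimulationConfig(snp_rate_background=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_sv_per_class={"deletion_mh": -1})


class TestSimulateSVs:
    def test_te_motif_at_minus_one(self):
        cfg = small_config(n_sv_per_class={"te_insertion": 50, "deletion_mh": 0,
                                           "simple_repeat": 0, "inversion": 0})
        ref, ann = generate_reference(cfg)
        records, manifest = simulate_svs(ref, ann, cfg)
        assert len(records) == 50
        for sv in manifest.svs:
            p = sv["start"]
            assert ref[sv["chrom"]][p - 1:p + 4] == cfg.te_target_motif

    def test_microhomology_point_mass(self):
        cfg = small_config(mh_length_distribution={8: 1.0},
                           n_sv_per_class={"te_insertion": 0, "deletion_mh": 20,
                                           "simple_repeat": 0, "inversion": 0})
        ref, ann = generate_reference(cfg)
        records, manifest = simulate_svs(ref, ann, cfg)
        for sv in manifest.svs:
            s, e = sv["start"], sv["end"]
            left = ref[sv["chrom"]][s - 8:s]
            right = ref[sv["chrom"]][e:e + 8]
            assert left == right == sv["determinant"]["mh_seq"]

    def test_inversions_cluster_at_hotspots(self):
        cfg = SimulationConfig(seed=9, n_chromosomes=2, chrom_length=150_000,
                               hotspot_count=2, hotspot_sd=1500.0, n_genes=20,
                               n_sv_per_class={"te_insertion": 0, "deletion_mh": 0,
                                               "simple_repeat": 0, "inversion": 100})
        ref, ann = generate_reference(cfg)
        _, manifest = simulate_svs(ref, ann, cfg)
        centers = {(h["chrom"], h["id"]): h["center"] for h in manifest.hotspots}
        near = sum(abs(sv["start"] - centers[(sv["chrom"],
                                              sv["determinant"]["hotspot_id"])])
                   <= 3 * cfg.hotspot_sd for sv in manifest.svs)
        assert near >= 0.8 * len(manifest.svs)

    def test_no_shared_breakpoints_and_counts(self, default_sim):
        bps = [(r.chrom, bp) for r in default_sim.records for bp in r.breakpoints]
        assert len(bps) == len(set(bps))
        per_class = {}
        for sv in default_sim.manifest.svs:
            per_class[sv["class"]] = per_class.get(sv["class"], 0) + 1
        assert per_class == default_sim.config.n_sv_per_class


class TestSmallVariants:
    def _density(self, ref, records, out, halo):
        near = np.zeros(0, dtype=bool)
        masks = {}
        for chrom in sorted(ref.keys()):
            m = np.zeros(len(ref[chrom]), dtype=bool)
            for r in records:
                if r.chrom == chrom:
                    for bp in r.breakpoints:
                        m[max(bp - halo, 0):bp + halo] = True
            masks[chrom] = m
        n_near = sum(int(masks[c].sum()) for c in masks)
        n_far = sum(len(masks[c]) - int(masks[c].sum()) for c in masks)
        hits_near = sum(int(masks[c][out["snp"][c]].sum()) for c in masks)
        hits_far = sum(len(out["snp"][c]) - int(masks[c][out["snp"][c]].sum())
                       for c in masks)
        return hits_near / n_near, hits_far / n_far

    def test_tenfold_elevation_recovered(self):
        cfg = SimulationConfig(seed=17, n_chromosomes=2, chrom_length=400_000,
                               snp_rate_background=0.005, snp_rate_near_bp=0.05,
                               breakpoint_halo=200, n_genes=20,
                               n_sv_per_class={"te_insertion": 50, "deletion_mh": 50,
                                               "simple_repeat": 0, "inversion": 0})
        res = simulate_fixture(cfg)
        d_near, d_far = self._density(res.reference, res.records,
                                      res.small_variants, 200)
        n_sites = sum(len(v) for v in res.small_variants["snp"].values())
        assert n_sites >= 5000
        assert 6 <= d_near / d_far <= 14

    def test_null_case_no_elevation(self):
        cfg = small_config(snp_rate_background=0.005, snp_rate_near_bp=0.005)
        res = simulate_fixture(cfg)
        d_near, d_far = self._density(res.reference, res.records,
                                      res.small_variants, cfg.breakpoint_halo)
        se = np.sqrt(0.005 / 10_000)   # conservative scale for both densities
        assert abs(d_near - d_far) < 2 * 3 * se

    def test_zero_rate_empty(self):
        cfg = small_config(snp_rate_background=0.0, snp_rate_near_bp=0.0)
        ref, ann = generate_reference(cfg)
        records, _ = simulate_svs(ref, ann, cfg)
        out = simulate_small_variants(ref, records, cfg)
        assert all(len(v) == 0 for sets in out.values() for v in sets.values())


class TestGenesAndConstraint:
    def test_zero_noise_is_linear_in_sv_count(self):
        cfg = small_config(constraint_noise_sd=0.0)
        res = simulate_fixture(cfg)
        t = res.gene_table
        expected = cfg.constraint_intercept - cfg.constraint_slope * t["n_sv"]
        assert np.allclose(t["constraint_score"], expected)
        # strictly decreasing in count
        g = t.groupby("n_sv")["constraint_score"].mean().sort_index()
        assert (np.diff(g.to_numpy()) < 0).all() or len(g) == 1

    def test_noisy_scores_anticorrelate_with_sv_count(self, default_sim):
        t = default_sim.gene_table
        rho = stats.spearmanr(t["constraint_score"], t["n_sv"]).statistic
        assert rho < 0

    def test_no_svs_scores_equal_intercept(self):
        cfg = small_config(constraint_noise_sd=0.0,
                           n_sv_per_class={c: 0 for c in
                                           ("te_insertion", "deletion_mh",
                                            "simple_repeat", "inversion")})
        res = simulate_fixture(cfg)
        assert np.allclose(res.gene_table["constraint_score"],
                           cfg.constraint_intercept)

    def test_determinant_sites_get_higher_af(self, default_sim):
        cls = {sv["id"]: sv["class"] for sv in default_sim.manifest.svs}
        det = [r.allele_frequency for r in default_sim.records
               if cls[r.id] in ("te_insertion", "deletion_mh")]
        other = [r.allele_frequency for r in default_sim.records
                 if cls[r.id] not in ("te_insertion", "deletion_mh")]
        assert np.mean(det) > np.mean(other)


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory, default_sim):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(d, default_sim)
    return d


class TestWriteFixture:
    def test_sv_vcf_round_trip(self, fixture_dir, default_sim):
        records = svio.read_sv_vcf(fixture_dir / "svs.vcf")
        got = {(r.chrom, r.start, r.end, r.svtype) for r in records}
        want = {(r.chrom, r.start, r.end, r.svtype) for r in default_sim.records}
        assert got == want

    def test_vcf_positions_are_one_based(self, tmp_path):
        rec = SVRecord(chrom="chr1", start=100, end=150, svtype="DEL",
                       length=50, id="d0")
        svio.write_sv_vcf(tmp_path / "one.vcf", [rec], {"chr1": 1000})
        line = [l for l in (tmp_path / "one.vcf").read_text().splitlines()
                if not l.startswith("#")][0]
        assert line.split("\t")[1] == "101"
        back = svio.read_sv_vcf(tmp_path / "one.vcf")[0]
        assert (back.start, back.end) == (100, 150)

    def test_bedgraph_sorted_and_nonoverlapping(self, fixture_dir):
        track = svio.read_bedgraph(fixture_dir / "conservation.bedGraph")
        for chrom in track.chroms():
            segs = track.segments(chrom)
            for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
                assert s1 < e1 <= s2 < e2

    def test_manifest_closure(self, fixture_dir):
        """Every planted determinant is recoverable from the files alone."""
        reference, records, bundle, gene_table, manifest = load_fixture(fixture_dir)
        by_id = {r.id: r for r in records}
        for sv in manifest.svs:
            assert sv["id"] in by_id
            det = sv["determinant"]
            chrom = sv["chrom"]
            if det["kind"] == "te_motif":
                s = det["motif_start"]
                assert str(reference[chrom][s:s + len(det["motif"])]) == det["motif"]
            elif det["kind"] == "microhomology":
                k = det["length"]
                assert (str(reference[chrom][sv["start"] - k:sv["start"]])
                        == str(reference[chrom][sv["end"]:sv["end"] + k])
                        == det["mh_seq"])
            elif det["kind"] == "repeat_overlap":
                rs, re_ = det["interval"]
                assert bundle.intervals["simple_repeat"].overlaps(chrom, rs, re_)

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = small_config()
        for sub in ("a", "b"):
            write_fixture(tmp_path / sub, simulate_fixture(cfg))
        for name in ("reference.fa", "svs.vcf", "small_variants.vcf",
                     "conservation.bedGraph", "gene_scores.tsv", "manifest.json"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name
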