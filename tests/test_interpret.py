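"""Perturbation/attribution suite: formula-level examples, machinery
direction checks on analytic stub models, and purity invariants."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from svcontext.dataset import GenomicWindow
from svcontext.errors import ConfigurationError
from svcontext.interpret import (correlation_matrix,
                                 empirical_breakpoint_homology,
                                 generate_nonb_motifs, importance_shift,
                                 insert_motif, ism, jsd, jsd_from_histograms,
                                 kmer_enrichment, kmer_insertion_scan,
                                 microhomology_scan, nonb_insertion_effect,
                                 pair_similarity, permutation_importance,
                                 substitution_motif_effect)
from svcontext.models import train_tabular


class GCStub:
    """Analytic model: probability = G-fraction of the sequence."""

    def predict_seqs(self, seqs):
        return [s.count("G") / len(s) for s in seqs]


class HomologyStub:
    """Probability = best symmetric k-mer match around the centre."""

    def __init__(self, k):
        self.k = k

    def predict_seqs(self, seqs):
        out = []
        for s in seqs:
            c, k = len(s) // 2, self.k
            best = 0.0
            for d in range(0, len(s) // 2 - k):
                best = max(best, pair_similarity(s[c - d - k:c - d],
                                                 s[c + d:c + d + k]))
            out.append(best)
        return out


def _random_windows(n, L=60, seed=0):
    r = np.random.default_rng(seed)
    return ["".join(r.choice(list("ACGT"), size=L)) for _ in range(n)]


class TestKmerEnrichment:
    def test_identical_sets_give_zero(self):
        w = _random_windows(5)
        df = kmer_enrichment(w, w, 3)
        assert np.allclose(df["enrichment"], 0.0)

    def test_absent_kmer_zero_with_pseudocounts(self):
        df = kmer_enrichment(["AAAA"], ["AAAA"], 2)
        row = df[df.kmer == "GC"].iloc[0]
        assert row["count_sv"] == row["count_bg"] == 0
        assert row["enrichment"] == 0.0

    def test_three_vs_one_equal_totals(self):
        # counts 3 vs 1 with equal totals and pseudocount 1 -> log2(2) = 1
        df = kmer_enrichment(["AAAC"], ["ACCC"], 1)
        assert df[df.kmer == "A"].iloc[0]["enrichment"] == pytest.approx(1.0)

    def test_invalid_k(self):
        with pytest.raises(ConfigurationError):
            kmer_enrichment(["AAAA"], ["AAAA"], 0)


class TestInsertMotif:
    def test_empty_motif_identity(self):
        assert insert_motif("ACGTACGT", "", 3) == "ACGTACGT"

    def test_right_trim_example(self):
        assert insert_motif("AAAATTTT", "GG", 6) == "AAAATTGG"

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 19), st.text(alphabet="ACGT", min_size=0, max_size=8))
    def test_length_preserved_and_center_kept(self, pos, motif):
        seq = "ACGTACGTACGTACGTACGT"          # L=20, centre index 10
        out = insert_motif(seq, motif, pos)
        assert len(out) == len(seq)
        if pos != len(seq) // 2:
            assert out[10] == seq[10]


class TestKmerInsertionScan:
    def test_enumerates_and_counts(self):
        res = kmer_insertion_scan(GCStub(), _random_windows(2), k=2,
                                  n_positions=3, seed=0)
        assert len(res) == 16
        assert all(r.n_insertions == 6 for r in res)

    def test_gc_stub_direction(self):
        res = kmer_insertion_scan(GCStub(), _random_windows(3), k=2,
                                  n_positions=5, seed=0)
        by = {r.motif: r.mean_delta for r in res}
        assert by["GG"] > by["AA"]

    def test_planted_motif_in_top_decile(self, te_trained):
        """The insertion scan ranks the planted endonuclease motif among
        the strongest 5-mers for the TE-trained model."""
        windows, _, bundle = te_trained
        bg = [w for w in windows if w.label == "background"][:4]
        res = kmer_insertion_scan(bundle.cnn, bg, k=5, n_positions=5, seed=0)
        df = pd.DataFrame([(r.motif, r.mean_delta) for r in res],
                          columns=["kmer", "delta"])
        rank = df["delta"].rank(pct=True)[df["kmer"] == "TAAAA"].iloc[0]
        assert rank >= 0.9


class TestMicrohomology:
    def test_pair_similarity_values(self):
        assert pair_similarity("AAAA", "AAAA") == 1.0
        assert pair_similarity("AAAA", "TTTT") == 0.0
        assert pair_similarity("AATT", "AAAA") == 0.5
        with pytest.raises(ConfigurationError):
            pair_similarity("AA", "AAA")

    def test_bookkeeping_and_identity_bin(self):
        w = _random_windows(2, L=40)
        table, binned, _ = microhomology_scan(GCStub(), w, k=4, n_pairs=10,
                                              n_distances=6, seed=1)
        assert (table["n_insertions"] == 12).all()
        ident = table[table["identity"]]
        assert (ident["kmer"] == ident["kmer2"]).all()
        assert "identity" in set(binned["bin"].astype(str))

    def test_homology_stub_shows_positive_trend(self):
        """A model that genuinely scores symmetric homology produces a
        positive similarity trend through the scan machinery."""
        w = _random_windows(3, L=60, seed=2)
        _, _, (rho, p) = microhomology_scan(HomologyStub(6), w, k=6,
                                            n_pairs=60, n_distances=10, seed=2)
        assert rho > 0 and p < 0.05

    def test_purity(self):
        w = [GenomicWindow(seq="ACGT" * 10, chrom="c", anchors=(100,),
                           label="background")]
        before = w[0].seq
        microhomology_scan(GCStub(), w, k=3, n_pairs=4, n_distances=3, seed=0)
        kmer_insertion_scan(GCStub(), w, k=2, n_positions=2, seed=0)
        assert w[0].seq == before

    def test_trained_model_prefers_identical_adjacent_pairs(self, mh_trained):
        """In the trained junction geometry (adjacent tandem, d=0) the
        deletion model responds more to identical than mismatched pairs."""
        from svcontext.interpret import _paired_insert, _predict
        windows, _, bundle = mh_trained
        bg = [w.seq for w in windows if w.label == "background"][:6]
        r = np.random.default_rng(0)
        gaps = []
        for _ in range(40):
            m = "".join(r.choice(list("ACGT"), size=8))
            m2 = "".join(r.choice(list("ACGT"), size=8))
            mods_id = [_paired_insert(s, m, m, 0) for s in bg]
            mods_mm = [_paired_insert(s, m, m2, 0) for s in bg]
            gaps.append(np.mean(_predict(bundle.cnn, mods_id))
                        - np.mean(_predict(bundle.cnn, mods_mm)))
        assert np.mean(gaps) > 0

    def test_empirical_homology_separates_planted_deletions(self, mh_trained):
        windows, _, _ = mh_trained
        sv = [w for w in windows if w.label == "sv"][:300]
        bg = [w for w in windows if w.label == "background"][:300]
        df = empirical_breakpoint_homology(sv, bg, k=8)
        top = df[df["sim_high"] >= 0.999]
        sv_mass = top[top.group == "sv"]["frequency"].sum()
        bg_mass = top[top.group == "background"]["frequency"].sum()
        assert sv_mass > bg_mass + 0.5
        for g in ("sv", "background"):
            assert df[df.group == g]["frequency"].sum() == pytest.approx(1.0)


G4_PATTERN = re.compile(r"G{3,}.{1,7}G{3,}.{1,7}G{3,}.{1,7}G{3,}")


def _alternating_fraction(s):
    pur = [c in "AG" for c in s]
    steps = sum(a != b for a, b in zip(pur, pur[1:]))
    return steps / (len(s) - 1)


class TestNonB:
    def test_g4_motifs_match_canonical_pattern(self):
        motifs = generate_nonb_motifs("G4", n=100, seed=0)
        assert len(set(motifs)) == 100
        assert all(G4_PATTERN.search(m) for m in motifs)

    def test_zdna_alternation(self):
        motifs = generate_nonb_motifs("ZDNA", n=100, seed=0)
        assert len(set(motifs)) == 100
        assert all(_alternating_fraction(m) >= 0.9 for m in motifs)
        assert _alternating_fraction("GC" * 10) == 1.0   # (GC)10 qualifies
        assert all("AAAA" not in m for m in motifs)

    def test_controls_match_lengths_and_direction_on_stub(self):
        motifs = generate_nonb_motifs("G4", n=10, seed=1)
        eff, ctl = nonb_insertion_effect(GCStub(), _random_windows(2, L=120),
                                         motifs,
                                         n_positions=4, seed=1)
        assert eff.n_insertions == ctl.n_insertions == 10 * 2 * 4
        assert eff.mean_delta > ctl.mean_delta     # G-rich beats random

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            generate_nonb_motifs("triplex", n=5)


class TestISM:
    def test_shape_and_reference_cells_zero(self):
        windows = _random_windows(3, L=64)
        m = ism(GCStub(), windows, radius=10)
        assert m.matrix.shape == (21, 4)
        for oi, off in enumerate(m.offsets):
            for bi, base in enumerate(m.base_order):
                # cells where every window already has `base` must be 0
                if all(s[len(s) // 2 + off] == base for s in windows):
                    assert m.matrix[oi, bi] == 0.0
        assert np.allclose(m.nucleotide_freqs.sum(axis=1), 1.0)

    def test_radius_bounds(self):
        with pytest.raises(ConfigurationError):
            ism(GCStub(), _random_windows(1, L=20), radius=30)

    def test_substitution_effect_enumeration_and_resident_zero(self):
        windows = ["ACGT" * 16]                  # resident centre 4-mer known
        df = substitution_motif_effect(GCStub(), windows)
        assert len(df) == 256
        c = 32
        resident = windows[0][c - 1:c + 3]
        assert df[df.motif == resident].iloc[0]["mean_delta"] == 0.0


class TestImportances:
    def _fit(self, n=400, seed=0):
        r = np.random.default_rng(seed)
        y = r.integers(0, 2, n)
        df = pd.DataFrame({"signal": y + r.normal(0, 0.1, n),
                           "noise": r.normal(size=n)})
        return train_tabular(df, y, "forest", seed=seed), df, y

    def test_identity_permutation_is_zero(self):
        model, df, y = self._fit()
        recs = permutation_importance(model, df, y, n_repeats=2,
                                      permuter=lambda rng, n: np.arange(n))
        assert all(r.permutation_mean == 0.0 for r in recs)

    def test_separating_feature_dominates(self):
        model, df, y = self._fit()
        recs = {r.feature: r for r in permutation_importance(model, df, y,
                                                             seed=1)}
        assert recs["signal"].permutation_mean > recs["noise"].permutation_mean
        assert recs["signal"].permutation_mean > 0.2
        assert all(r.permutation_sd >= 0 for r in recs.values())

    def test_importance_shift_alignment(self):
        model, df, y = self._fit()
        recs = permutation_importance(model, df, y, seed=2)
        shift = importance_shift(recs, recs)
        assert np.allclose(shift["delta"].dropna(), 0.0)
        with pytest.raises(ConfigurationError):
            importance_shift(recs, recs[:1])


class TestJSD:
    def test_identical_and_disjoint(self):
        r = np.random.default_rng(0)
        x = r.normal(size=500)
        assert jsd(x, x).value == pytest.approx(0.0, abs=1e-12)
        assert jsd(np.zeros(100), np.ones(100), n_bins=4).value == pytest.approx(1.0)

    def test_prebinned_worked_example(self):
        assert jsd_from_histograms([1, 0], [0.5, 0.5]) == pytest.approx(
            0.3113, abs=2e-4)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_bounded(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=50), r.normal(1, 2, size=50)
        ja, jb = jsd(a, b).value, jsd(b, a).value
        assert ja == pytest.approx(jb, abs=1e-12)
        assert 0.0 <= ja <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            jsd([], [1.0])


class TestCorrelationMatrix:
    def test_diagonal_monotone_and_constant_flag(self):
        r = np.random.default_rng(1)
        x = r.normal(size=100)
        df = pd.DataFrame({"x": x, "neg": -np.exp(x), "const": np.ones(100)})
        mat, flagged = correlation_matrix(df)
        assert np.allclose(np.diag(mat), 1.0)
        assert mat.loc["x", "neg"] == pytest.approx(-1.0)
        assert flagged == ["const"]
        assert mat.loc["x", "const"] == 0.0
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
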