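"""Sequence-guided superposition, RMSD/TM-score and the sampling pipeline."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from isodom.struct_compare import (
    DomainStructure,
    RejectedComparison,
    StructuralComparison,
    align_domain_sequences,
    compare_structures,
    kabsch_superpose,
    load_domain_structure,
    sample_comparisons,
    summarize_structural_differences,
    tm_d0,
    unrelated_baseline,
    write_pdb,
)
from isodom.synthetic_data import helix_backbone, random_sequence, simulate_structures


def make_structure(seq, coords, isotype="reference", sid="S", name="Dom"):
    return DomainStructure(
        structure_id=sid, chain_id="A", residue_ids=np.arange(1, len(seq) + 1),
        sequence=seq, backbone_coords=coords, isotype=isotype, hmm_name=name,
    )


@pytest.fixture
def helix35():
    rng = np.random.default_rng(42)
    seq = random_sequence(35, rng)
    return make_structure(seq, helix_backbone(35), sid="REF")


def rigid_copy(s, seed, sid="COPY", isotype="reference"):
    rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
    shift = np.array([7.0, -11.0, 3.0])
    return make_structure(s.sequence, s.backbone_coords @ rot.T + shift, isotype, sid, s.hmm_name)


def oracle_scores(a, b):
    """Independent route: scipy's Kabsch (align_vectors) plus a per-residue
    TM-score loop, from the sequence alignment onward."""
    pairs = align_domain_sequences(a.sequence, b.sequence)
    P = a.backbone_coords[[i for i, _ in pairs]]
    Q = b.backbone_coords[[j for _, j in pairs]]
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(P - cp, Q - cq)
    Qf = rot.apply(Q - cq) + cp
    rmsd = float(np.sqrt(np.mean(np.sum((Qf - P) ** 2, axis=1))))
    L = len(a.sequence)
    d0 = 1.24 * (L - 15) ** (1 / 3) - 1.8 if L > 15 else 0.5
    d0 = max(d0, 0.5)
    tm = sum(1.0 / (1.0 + (np.linalg.norm(qi - pi) / d0) ** 2) for pi, qi in zip(P, Qf)) / L
    return rmsd, tm


class TestLoad:
    def test_domain_range_slicing(self, tmp_path):
        rng = np.random.default_rng(0)
        s = make_structure(random_sequence(60, rng), helix_backbone(60))
        p = tmp_path / "helix.pdb"
        write_pdb(s, p)
        dom = load_domain_structure(p, aln_start=10, aln_end=40)
        assert len(dom) == 31
        assert dom.sequence == s.sequence[9:40]
        np.testing.assert_allclose(dom.backbone_coords, s.backbone_coords[9:40], atol=1e-3)

    def test_unknown_residue_excluded_but_positions_preserved(self, tmp_path):
        rng = np.random.default_rng(1)
        s = make_structure(random_sequence(20, rng), helix_backbone(20))
        p = tmp_path / "withx.pdb"
        write_pdb(s, p)
        # replace residue 10 with UNK (one-letter X)
        lines = p.read_text().splitlines()
        lines[10] = lines[10].replace(f"CA  {_res3(s.sequence[9])} A", "CA  UNK A")
        p.write_text("\n".join(lines) + "\n")
        dom = load_domain_structure(p, aln_start=1, aln_end=20)
        assert len(dom) == 19
        assert 10 not in dom.residue_ids.tolist()
        # positions after the X keep their original indices
        assert dom.residue_ids[-1] == 20

    def test_first_model_only(self, tmp_path):
        rng = np.random.default_rng(2)
        s1 = make_structure(random_sequence(12, rng), helix_backbone(12))
        s2 = make_structure(s1.sequence, helix_backbone(12) + 50.0)
        p = tmp_path / "two_models.pdb"
        body1 = _atom_block(s1, serial0=1)
        body2 = _atom_block(s2, serial0=100)
        p.write_text(
            "MODEL        1\n" + body1 + "ENDMDL\nMODEL        2\n" + body2 + "ENDMDL\nEND\n"
        )
        dom = load_domain_structure(p, aln_start=1, aln_end=12)
        np.testing.assert_allclose(dom.backbone_coords, s1.backbone_coords, atol=1e-3)

    def test_missing_chain_raises(self, tmp_path):
        rng = np.random.default_rng(3)
        s = make_structure(random_sequence(10, rng), helix_backbone(10))
        p = tmp_path / "c.pdb"
        write_pdb(s, p)
        with pytest.raises(ValueError):
            load_domain_structure(p, chain="Z")

    def test_empty_selection_raises(self, tmp_path):
        rng = np.random.default_rng(4)
        s = make_structure(random_sequence(10, rng), helix_backbone(10))
        p = tmp_path / "e.pdb"
        write_pdb(s, p)
        with pytest.raises(ValueError):
            load_domain_structure(p, aln_start=50, aln_end=60)


def _res3(aa):
    from isodom.struct_compare import _AA3

    return _AA3[aa]


def _atom_block(s, serial0=1):
    out = []
    for i, (aa, xyz) in enumerate(zip(s.sequence, s.backbone_coords)):
        out.append(
            f"ATOM  {serial0 + i:5d}  CA  {_res3(aa)} A{i + 1:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
        )
    return "".join(out)


class TestCompare:
    def test_identity(self, helix35):
        copy = make_structure(helix35.sequence, helix35.backbone_coords.copy(), sid="C")
        res = compare_structures(helix35, copy)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert res.tm_score == pytest.approx(1.0, abs=1e-10)
        assert res.aligned_length == 35

    def test_rigid_invariance(self, helix35):
        res = compare_structures(helix35, rigid_copy(helix35, seed=5))
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        assert res.tm_score == pytest.approx(1.0, abs=1e-8)

    def test_d0_value(self):
        assert tm_d0(35) == pytest.approx(1.24 * 20 ** (1 / 3) - 1.8)
        assert tm_d0(10) == 0.5

    def test_noise_rmsd_range_and_oracle(self, helix35):
        """i.i.d. N(0, 0.5^2) coordinate noise: RMSD near sqrt(3)*0.5, and both
        scores equal an independent scipy-based oracle."""
        rng = np.random.default_rng(6)
        rmsds = []
        for _ in range(100):
            noisy = make_structure(
                helix35.sequence,
                helix35.backbone_coords + rng.normal(0, 0.5, (35, 3)),
                sid="N",
            )
            res = compare_structures(helix35, noisy)
            o_rmsd, o_tm = oracle_scores(helix35, noisy)
            assert res.rmsd == pytest.approx(o_rmsd, abs=1e-8)
            assert res.tm_score == pytest.approx(o_tm, abs=1e-8)
            rmsds.append(res.rmsd)
        assert all(0.6 <= r <= 1.2 for r in rmsds)

    def test_short_alignment_rejected(self, helix35):
        frag = make_structure(helix35.sequence[:15], helix35.backbone_coords[:15], sid="F")
        res = compare_structures(helix35, frag)
        assert isinstance(res, RejectedComparison)
        assert res.reason == "min_aln_len"

    def test_coverage_is_measured_on_nonreference(self, helix35):
        """A truncated suffix aligns fully, so its own coverage is 1 and only
        the alignment-length filter can reject it."""
        trunc = make_structure(
            helix35.sequence[11:], helix35.backbone_coords[11:], sid="T", isotype="truncation"
        )
        res = compare_structures(helix35, trunc)
        assert isinstance(res, StructuralComparison)
        assert res.coverage_nonref == pytest.approx(1.0)
        assert res.aligned_length == 24

    def test_coverage_filter_fires_on_partial_alignment(self, helix35):
        # non-reference longer than the alignable region: coverage < 0.8
        rng = np.random.default_rng(7)
        extra = random_sequence(15, rng)
        seq = helix35.sequence[:25] + extra
        coords = np.vstack([helix35.backbone_coords[:25], helix_backbone(15) + 100.0])
        b = make_structure(seq, coords, sid="P", isotype="insertion")
        res = compare_structures(helix35, b)
        if isinstance(res, StructuralComparison):
            assert res.coverage_nonref > 0.8
        else:
            assert res.reason == "coverage"

    def test_kabsch_optimality_vs_random_transforms(self, helix35):
        rng = np.random.default_rng(8)
        noisy = helix35.backbone_coords + rng.normal(0, 1.0, (35, 3))
        _, best = kabsch_superpose(helix35.backbone_coords, noisy)
        rots = Rotation.random(1000, rng=rng)
        centered = noisy - noisy.mean(axis=0)
        target = helix35.backbone_coords - helix35.backbone_coords.mean(axis=0)
        for rot in rots:
            rmsd = np.sqrt(np.mean(np.sum((rot.apply(centered) - target) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_degenerate_superposition(self):
        a = make_structure("AC", helix_backbone(2), sid="A")
        b = make_structure("AC", helix_backbone(2), sid="B")
        with pytest.raises(ValueError):
            compare_structures(a, b, min_aln_len=0)


class TestSampling:
    def test_small_counts(self):
        structs, _ = simulate_structures(n_ref=3, n_nonref=2, noise_sd=0.1, truncate_frac=0.1, seed=9)
        passed, rejected = sample_comparisons({"SynthHelix": structs})
        classes = [c.pair_class for c in passed] + [r.pair_class for r in rejected]
        assert classes.count("ref_vs_nonref") == 6
        assert classes.count("ref_vs_ref") == 3

    def test_caps(self):
        structs, _ = simulate_structures(
            n_ref=12, n_nonref=30, noise_sd=0.05, truncate_frac=0.1, seed=10
        )
        passed, rejected = sample_comparisons({"SynthHelix": structs})
        classes = [c.pair_class for c in passed] + [r.pair_class for r in rejected]
        assert classes.count("ref_vs_nonref") == 9 * 21
        assert classes.count("ref_vs_ref") == 36

    def test_no_nonref_yields_only_ref_pairs(self):
        structs, _ = simulate_structures(n_ref=1, n_nonref=0, noise_sd=0.1, seed=11)
        passed, rejected = sample_comparisons({"SynthHelix": structs})
        assert passed == [] and rejected == []

    def test_seed_reproducibility(self):
        structs, _ = simulate_structures(n_ref=12, n_nonref=25, noise_sd=0.2, truncate_frac=0.1, seed=12)
        p1, _ = sample_comparisons({"SynthHelix": structs}, seed=3)
        p2, _ = sample_comparisons({"SynthHelix": structs}, seed=3)
        assert [c.pair for c in p1] == [c.pair for c in p2]


class TestSummarize:
    def test_mean_and_threshold(self, helix35):
        rng = np.random.default_rng(13)
        comps = []
        for k in range(5):
            noisy = make_structure(
                helix35.sequence, helix35.backbone_coords + rng.normal(0, 0.3, (35, 3)),
                sid=f"N{k}", isotype="truncation",
            )
            comps.append(compare_structures(helix35, noisy))
        table = summarize_structural_differences(comps)
        assert len(table) == 1
        assert table.loc[0, "n"] == 5
        assert table.loc[0, "mean_rmsd"] == pytest.approx(np.mean([c.rmsd for c in comps]))
        # fewer than 3 comparisons: no row
        assert len(summarize_structural_differences(comps[:2])) == 0

    def test_noisier_nonref_has_larger_mean_rmsd(self):
        wins = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            seq = random_sequence(35, rng)
            base = helix_backbone(35)
            ref = [
                make_structure(seq, base + rng.normal(0, 0.3, base.shape), "reference", f"R{k}")
                for k in range(3)
            ]
            non = [
                make_structure(seq, base + rng.normal(0, 0.9, base.shape), "deletion", f"D{k}")
                for k in range(3)
            ]
            by_dom = {"Dom": ref + non}
            passed, _ = sample_comparisons(by_dom, seed=seed)
            table = summarize_structural_differences(passed).set_index("isotype")
            if table.loc["deletion", "mean_rmsd"] > table.loc["reference", "mean_rmsd"]:
                wins += 1
        assert wins >= 28

    def test_mean_tm_decreases_with_noise(self, helix35):
        means = []
        for sigma in (0.25, 0.5, 1.0, 2.0):
            rng = np.random.default_rng(14)
            tms = []
            for _ in range(30):
                noisy = make_structure(
                    helix35.sequence, helix35.backbone_coords + rng.normal(0, sigma, (35, 3)),
                    sid="N",
                )
                tms.append(compare_structures(helix35, noisy).tm_score)
            means.append(np.mean(tms))
        assert means == sorted(means, reverse=True)

    def test_tm_rmsd_negative_rank_correlation(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(15)
        seq = random_sequence(35, rng)
        base = helix_backbone(35)
        a = make_structure(seq, base, sid="A")
        rmsds, tms = [], []
        for sigma in np.linspace(0.2, 2.0, 20):
            noisy = make_structure(seq, base + rng.normal(0, sigma, base.shape), sid="B")
            res = compare_structures(a, noisy)
            rmsds.append(res.rmsd)
            tms.append(res.tm_score)
        rho = spearmanr(rmsds, tms).statistic
        assert rho < 0


class TestBaseline:
    def _structures(self, n_domains, seed):
        rng = np.random.default_rng(seed)
        out = []
        for d in range(n_domains):
            seq = random_sequence(30, rng)
            coords = helix_backbone(30) + rng.normal(0, 1.5, (30, 3))
            out.append(make_structure(seq, coords, "reference", f"S{d}", f"DOM{d:03d}"))
        return out

    def test_determinism(self):
        structs = self._structures(8, seed=16)
        assert unrelated_baseline(structs, seed=5) == unrelated_baseline(structs, seed=5)

    def test_two_domains_collapse_to_single_value(self):
        structs = self._structures(2, seed=17)
        (r_lo, r_hi), (t_lo, t_hi) = unrelated_baseline(structs, seed=1, min_coverage=0.0, min_aln_len=10)
        assert r_lo == pytest.approx(r_hi)
        assert t_lo == pytest.approx(t_hi)

    def test_insufficient_domains(self):
        structs = self._structures(1, seed=18)
        with pytest.raises(ValueError):
            unrelated_baseline(structs, seed=1)
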