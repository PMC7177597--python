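import numpy as np
import pytest

from pacfinder import filters, pipeline, scanner, synthetic_data as sd
from pacfinder.io_formats import _translate_cds


class TestGeneratePdp:
    def test_bit_reproducible(self):
        r1, t1 = sd.generate_pdp(3, 42)
        r2, t2 = sd.generate_pdp(3, 42)
        assert r1.sequence == r2.sequence
        assert t1 == t2

    def test_seed_changes_sequence(self):
        r1, _ = sd.generate_pdp(1, 1)
        r2, _ = sd.generate_pdp(1, 2)
        assert r1.sequence != r2.sequence

    @pytest.mark.parametrize("pdp_type", [1, 2, 3, 4])
    def test_truth_matches_scanner(self, pdp_type):
        for seed in range(8):
            rec, truth = sd.generate_pdp(pdp_type, seed)
            matches = scanner.scan_strict(rec)
            assert len(matches) == 1
            assert matches[0].span == truth.pac_span
            assert matches[0].cys_pos == truth.cys_positions

    def test_corruption_free_passes_all_gates(self, rng):
        for i in range(20):
            rec, truth = sd.generate_pdp(int(rng.integers(1, 5)), rng, record_id=f"g{i}")
            res = pipeline.run_record(rec)
            assert res.bona_fide
            assert res.gate_verdicts["signal_peptide"] == "pass"

    @pytest.mark.parametrize("corruption", ["missing_cys", "extra_cys",
                                            "gap_violation", "missing_gly"])
    def test_scaffold_corruptions_break_strict_scan(self, corruption, rng):
        for i in range(10):
            rec, _ = sd.generate_pdp(1, rng, corruption, record_id=f"{corruption}{i}")
            assert scanner.scan_strict(rec) == []

    def test_missing_cys_recovered_in_relaxed_mode(self, rng):
        rec, truth = sd.generate_pdp(1, rng, "missing_cys")
        tol = scanner.RelaxedTolerances(allow_missing_cys=True)
        ms = scanner.scan_relaxed(rec, tolerances=tol)
        assert any("missing_cys" in m.violations and m.cys_in_span == 5 for m in ms)

    def test_extra_cys_recovered_in_relaxed_mode(self, rng):
        rec, truth = sd.generate_pdp(1, rng, "extra_cys")
        tol = scanner.RelaxedTolerances(max_extra_cys=1)
        ms = scanner.scan_relaxed(rec, tolerances=tol)
        hits = [m for m in ms if "extra_cys_in_spacer" in m.violations]
        assert hits and hits[0].cys_in_span == 7

    def test_helix_decoy_fails_ss_gate(self, rng):
        for i in range(10):
            rec, _ = sd.generate_pdp(1, rng, "helix_decoy", record_id=f"hd{i}")
            (m,) = scanner.scan_strict(rec)
            track = filters.predict_ss_fallback(rec)
            assert filters.ss_admissible(m, track) == "fail"

    def test_no_signal_peptide_fails_gate(self, rng):
        for i in range(10):
            rec, _ = sd.generate_pdp(1, rng, "no_signal_peptide", record_id=f"ns{i}")
            assert filters.signal_peptide_gate(rec) == "fail"

    def test_foreign_domain_hit_fails_gate(self, rng):
        rec, truth = sd.generate_pdp(1, rng, "foreign_domain")
        hits = sd.domain_hits_for(rec, truth)
        assert len(hits) == 1 and hits[0].accession == "PF00171"
        assert filters.foreign_domain_gate(rec, hits) == "fail"

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_pdp(5, 1)
        with pytest.raises(ValueError):
            sd.generate_pdp(1, 1, corruption="typo")


class TestGenerateGeneModel:
    def test_cds_translates_to_protein(self, rng):
        for i in range(20):
            rec, truth = sd.generate_pdp(int(rng.integers(1, 5)), rng, record_id=f"t{i}")
            model, contig = sd.generate_gene_model(rec, truth, "none", rng)
            cds = "".join(contig[s - 1:e] for s, e in model.cds_segments)
            assert _translate_cds(cds) == rec.sequence + "*"

    def test_intron_has_canonical_splice_sites(self, rng):
        rec, truth = sd.generate_pdp(1, rng)
        model, contig = sd.generate_gene_model(rec, truth, "diagnostic", rng)
        (e1, e2) = model.exons
        intron = contig[e1[1]:e2[0] - 1]
        assert intron.startswith("GT") and intron.endswith("AG")

    def test_intronless_class(self, rng):
        rec, truth = sd.generate_pdp(1, rng)
        model, _ = sd.generate_gene_model(rec, truth, "none", rng)
        assert len(model.exons) == 1
        assert truth.intron_class == "none"

    def test_cds_length_divisible_by_three(self, rng):
        rec, truth = sd.generate_pdp(2, rng)
        model, _ = sd.generate_gene_model(rec, truth, "atypical", rng)
        assert model.cds_length % 3 == 0


class TestGenerateTandemCluster:
    def test_realized_identity_near_target(self):
        from pacfinder import similarity as sim

        for seed in range(10):
            records, truths, _ = sd.generate_tandem_cluster(3, 90.0, seed)
            span = truths[0].pac_span
            for i in range(3):
                for j in range(i + 1, 3):
                    a = records[i].sequence[span[0]:span[1]]
                    b = records[j].sequence[span[0]:span[1]]
                    ident = sim.global_align(a, b).identity_pct
                    assert abs(ident - 90.0) <= 3.0

    def test_genes_adjacent_on_one_scaffold(self):
        _, _, models = sd.generate_tandem_cluster(3, 92.0, 1)
        assert len({m.seq_id for m in models}) == 1
        starts = [m.genomic_start for m in models]
        assert starts == sorted(starts)

    def test_members_scan_cleanly(self):
        records, truths, _ = sd.generate_tandem_cluster(3, 92.0, 2)
        for rec, truth in zip(records, truths):
            (m,) = scanner.scan_strict(rec)
            assert m.span == truth.pac_span

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sd.generate_tandem_cluster(1, 92.0, 0)
        with pytest.raises(ValueError):
            sd.generate_tandem_cluster(2, 40.0, 0)


class TestGenerateStructure:
    def test_default_passes_bridge_check(self):
        from pacfinder import structure_qc as sq

        _, truth = sd.generate_pdp(1, 9)
        model = sd.generate_structure(truth)
        assert sq.check_disulfides(model, sd.cys_residue_indices(truth)).verdict == "pass"

    def test_swap_fails_bridge_check(self):
        from pacfinder import structure_qc as sq

        _, truth = sd.generate_pdp(1, 9)
        model = sd.generate_structure(truth, swap=True)
        assert sq.check_disulfides(model, sd.cys_residue_indices(truth)).verdict == "fail"

    def test_non_partner_sg_distances_large(self):
        _, truth = sd.generate_pdp(1, 9)
        model = sd.generate_structure(truth)
        sg = {a.residue_index: a.coords for a in model.atoms if a.atom_name == "SG"}
        ordinals = {v: k for k, v in sd.cys_residue_indices(truth).items()}
        partners = {frozenset(p) for p in [(1, 5), (3, 4), (2, 6)]}
        keys = sorted(sg)
        for i, ra in enumerate(keys):
            for rb in keys[i + 1:]:
                pair = frozenset((ordinals[ra], ordinals[rb]))
                d = np.linalg.norm(sg[ra] - sg[rb])
                if pair in partners:
                    assert d == pytest.approx(2.05, abs=1e-6)
                else:
                    assert d > 6.0
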