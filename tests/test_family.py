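"""Architecture detection, family precedence and group classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinascade import family as fam
from kinascade import simulate
from kinascade.family import PipelineConfig
from kinascade.motifs import builtin_registry, scan
from kinascade.seqio import ProteinRecord


def _rng(seed=0):
    return np.random.default_rng(seed)


def _first_activation(registry, name, seq):
    hits = scan(registry[name], seq)
    assert hits
    return hits[0]


@pytest.fixture(scope="module")
def registry():
    return builtin_registry()


def _planted(family_name, seed=0, **kwargs):
    cfg = simulate.SimulationConfig()
    reg = builtin_registry()
    return simulate.build_kinase(family_name, _rng(seed), cfg, reg, **kwargs)


class TestDetectArchitecture:
    def test_planted_loops_all_found_in_order(self, registry):
        seq, truth = _planted("MAPK", txy_variant="TEY")
        act = _first_activation(registry, "mapk_act", seq)
        arch = fam.detect_architecture(seq, act, registry)
        assert arch.p_loop and arch.c_loop and arch.t_loop
        assert arch.p_loop.start < arch.c_loop.start < arch.t_loop.start
        assert arch.loops_found == "PCT"

    def test_p_loop_after_activation_recorded_absent(self, registry):
        # P-loop present only downstream of the activation site: order violated
        rng = _rng(4)
        c_loop = simulate.sample_motif_instance(registry["c_loop"], rng)
        act = "TEYVATRWYRAPEL"
        p_loop = simulate.sample_motif_instance(registry["p_loop"], rng)
        seq = (
            simulate._random_peptide(rng, 30)
            + c_loop
            + simulate._random_peptide(rng, 20)
            + act
            + simulate._random_peptide(rng, 10)
            + p_loop
            + simulate._random_peptide(rng, 10)
        )
        hit = _first_activation(registry, "mapk_act", seq)
        arch = fam.detect_architecture(seq, hit, registry)
        assert arch.p_loop is None
        assert not fam.confirm_kinase_domain(arch, "confirmed")

    def test_txy_variant_extracted(self, registry):
        seq = "A" * 20 + "TEYVATRWYRAPEL" + "A" * 20
        hit = _first_activation(registry, "mapk_act", seq)
        arch = fam.detect_architecture(seq, hit, registry)
        assert arch.txy_variant == "TEY"

    def test_cdd_candidate_covers_tail(self, registry):
        seq, truth = _planted("MAPK", seed=2)
        hit = _first_activation(registry, "mapk_act", seq)
        arch = fam.detect_architecture(seq, hit, registry)
        assert arch.cdd_candidate == (hit.end, len(seq))

    def test_spacing_bounds_are_enforced(self, registry):
        # C-loop too close to the activation site (< 5 aa gap) is not accepted
        rng = _rng(9)
        c_loop = simulate.sample_motif_instance(registry["c_loop"], rng)
        seq = "A" * 60 + c_loop + "AA" + "TEYVATRWYRAPEL" + "A" * 30
        hit = _first_activation(registry, "mapk_act", seq)
        arch = fam.detect_architecture(seq, hit, registry)
        assert arch.c_loop is None


class TestConfirm:
    def test_canonical_spacing_confirms(self, registry):
        seq, _ = _planted("RAF", seed=1)
        hit = _first_activation(registry, "raf_act", seq)
        arch = fam.detect_architecture(seq, hit, registry)
        assert fam.confirm_kinase_domain(arch, "confirmed")

    def test_bare_activation_motif_is_loose_only(self, registry):
        seq = "A" * 40 + "TEYVATRWYRAPEL" + "A" * 40
        hit = _first_activation(registry, "mapk_act", seq)
        arch = fam.detect_architecture(seq, hit, registry)
        assert fam.confirm_kinase_domain(arch, "loose")
        assert not fam.confirm_kinase_domain(arch, "confirmed")

    def test_loose_p_loop_suffices_for_confirmation(self, registry):
        """Kinases lacking the strict P-loop still confirm via GxGxxG."""
        rng = _rng(5)
        c_loop = simulate.sample_motif_instance(registry["c_loop"], rng)
        seq = (
            "M" + "GAGAAG"  # loose P-loop only
            + "A" * 80
            + c_loop
            + "A" * 20
            + "TEYVATRWYRAPEL"
            + "A" * 30
        )
        hit = _first_activation(registry, "mapk_act", seq)
        arch = fam.detect_architecture(seq, hit, registry)
        assert arch.p_loop_kind == "loose"
        assert fam.confirm_kinase_domain(arch, "confirmed")


class TestAssignFamily:
    def test_zik_beats_mekk_on_shared_site(self, registry):
        seq, truth = _planted("ZIK", seed=3)
        call = fam.assign_family(ProteinRecord("z1", "z1", seq), registry)
        assert call.family == "ZIK"
        assert set(call.evidence) >= {"zik_act", "mekk_act"}
        assert call.evidence[0] == "zik_act"

    def test_published_raf_g_site_assigned_raf(self, registry):
        seq, _ = _planted("RAF", seed=6, raf_group="G")
        assert "GTRHYMAPEV" in seq
        call = fam.assign_family(ProteinRecord("r1", "r1", seq), registry)
        assert call.family == "RAF"

    def test_random_decoy_gets_no_family(self, registry):
        seq, _ = simulate.build_random_decoy(_rng(8), registry)
        call = fam.assign_family(ProteinRecord("d", "d", seq), registry)
        assert call.family is None
        assert call.evidence == ()

    def test_loose_mode_accepts_bare_motif(self, registry):
        seq = "A" * 40 + "TEYVATRWYRAPEL" + "A" * 40
        loose = fam.assign_family(
            ProteinRecord("p", "p", seq), registry, PipelineConfig(mode="loose")
        )
        confirmed = fam.assign_family(ProteinRecord("p", "p", seq), registry)
        assert loose.family == "MAPK" and not loose.confirmed
        assert confirmed.family is None


class TestMapkGroups:
    def _call(self, variant, seed=0):
        seq, truth = _planted("MAPK", seed=seed, txy_variant=variant)
        call = fam.assign_family(ProteinRecord("m", "m", seq))
        return call, call.architecture

    def test_tey_is_group_c(self):
        call, arch = self._call("TEY")
        assert fam.classify_mapk_group(call, arch).group == "C"

    def test_tsy_is_group_e(self):
        call, arch = self._call("TSY")
        gc = fam.classify_mapk_group(call, arch)
        assert gc.group == "E" and not gc.ambiguous_DE

    def test_tdy_without_tree_is_flagged_d(self):
        call, arch = self._call("TDY")
        gc = fam.classify_mapk_group(call, arch)
        assert gc.group == "D" and gc.ambiguous_DE and gc.basis == "rule"

    def test_tdy_resolved_by_anchor_tree(self):
        from skbio import TreeNode

        call, arch = self._call("TDY")
        tree = TreeNode.read(["((m:0.1,anchorE:0.2):0.5,(anchorD:0.3,x:0.4):0.5);"])
        gc = fam.classify_mapk_group(
            call, arch, tree=tree, anchors={"anchorD": "D", "anchorE": "E"}
        )
        assert gc.group == "E" and gc.basis == "tree"

    def test_non_mapk_rejected(self):
        seq, _ = _planted("RAF", seed=2)
        call = fam.assign_family(ProteinRecord("r", "r", seq))
        with pytest.raises(ValueError, match="not a MAPK"):
            fam.classify_mapk_group(call, call.architecture)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(variant=st.sampled_from(["TDY", "TTY", "TSY", "TPY"]), seed=st.integers(0, 5))
    def test_group_c_only_for_tey(self, variant, seed):
        call, arch = self._call(variant, seed=seed)
        assert fam.classify_mapk_group(call, arch).group != "C"


class TestRafGroups:
    def test_gtrhymapev_is_group_g(self):
        seq, _ = _planted("RAF", seed=7, raf_group="G")
        call = fam.assign_family(ProteinRecord("r", "r", seq))
        gc = fam.classify_raf_group(call, call.architecture, seq)
        assert gc.group == "G"

    def _loose_raf_call(self, seq):
        call = fam.assign_family(
            ProteinRecord("r", "r", seq), config=PipelineConfig(mode="loose")
        )
        assert call.family == "RAF"
        return call

    def test_group_h_signature(self):
        # H needs GTxxYMAPE(A/C/L/T) at the site and GxGxxGxV upstream
        seq = "M" + "GAGAAGAV" + "A" * 60 + "GTAAYMAPEL" + "A" * 30
        call = self._loose_raf_call(seq)
        gc = fam.classify_raf_group(call, call.architecture, seq)
        assert gc.group == "H"

    def test_group_a_vs_c_split_by_tail(self):
        rng = _rng(12)
        ploop_a = simulate.sample_motif_instance(fam.RAF_A_PLOOP, rng)
        core = "M" + ploop_a + "A" * 40 + "GTAAYMAPEV"
        short = core + "A" * 30
        long = core + "A" * 200
        for seq, expected in ((short, "A"), (long, "C")):
            call = self._loose_raf_call(seq)
            gc = fam.classify_raf_group(call, call.architecture, seq)
            assert gc.group == expected

    def test_heterogeneous_site_unassigned(self):
        seq, _ = _planted("RAF", seed=13)
        call = fam.assign_family(ProteinRecord("r", "r", seq))
        gc = fam.classify_raf_group(call, call.architecture, seq)
        assert gc.group == "unassigned"

    def test_non_raf_rejected(self):
        seq, _ = _planted("ZIK", seed=1)
        call = fam.assign_family(ProteinRecord("z", "z", seq))
        with pytest.raises(ValueError, match="not a RAF"):
            fam.classify_raf_group(call, call.architecture, seq)


class TestRunInventory:
    def test_counts_match_manifest(self, small_records, small_gene_models, small_sim):
        table, summary = fam.run_inventory(small_records, small_gene_models)
        cfg = small_sim["config"]
        assert summary["family_counts"] == {
            "MAPK": cfg.mapk, "MAPKK": cfg.mapkk, "MEKK": cfg.mekk,
            "RAF": cfg.raf, "ZIK": cfg.zik,
        }
        assert summary["mapkkk_total"] == cfg.mekk + cfg.raf + cfg.zik

    def test_row_order_is_input_order(self, small_records, small_gene_models):
        table, _ = fam.run_inventory(small_records, small_gene_models)
        assert list(table["id"]) == [r.id for r in small_records]

    def test_empty_proteome(self):
        table, summary = fam.run_inventory([])
        assert table.empty
        assert summary["family_counts"] == dict.fromkeys(fam.FAMILIES, 0)

    def test_missing_gene_model_leaves_genomic_fields_empty(self, small_records, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            table, _ = fam.run_inventory(small_records[:2], gene_models=[])
        assert (table["chromosome"] == "").all()

    def test_config_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            PipelineConfig.from_dict({"mode": "loose", "bogus": 1})
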