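"""Model data structures, I/O, FBA, task checking."""

import json

import numpy as np
import pytest

from conftest import oracle_max_flux
from contarget.errors import FormatError, ValidationError
from contarget.model_core import (MetabolicTask, check_task, delete_reactions,
                                  fba, is_viable, load_model, load_tasks,
                                  model_from_dict, model_to_dict, write_model,
                                  write_tasks)
from contarget.synthetic_data import generate_toy_gem, toy_tasks


class TestStructure:
    def test_toy1_counts(self, toy1):
        assert toy1.n_reactions == 7
        non_currency = [m for m in toy1.metabolite_ids
                        if m not in toy1.currency_ids]
        assert len(non_currency) == 5

    @pytest.mark.parametrize("mutate, match", [
        (lambda d: d["reactions"][1].update(rev=0, lb=-1.0), "lb < 0"),
        (lambda d: d["metabolites"].append("A[e]"), "duplicate"),
        (lambda d: d["reactions"][1].update(gpr=[["ghost"]]), "unknown gene"),
        (lambda d: d["currency"].append("missing[c]"), "currency"),
        (lambda d: d.update(objective="nope"), "objective"),
    ])
    def test_validation_rejects(self, toy1, mutate, match):
        doc = model_to_dict(toy1)
        mutate(doc)
        with pytest.raises(ValidationError, match=match):
            model_from_dict(doc)

    def test_reaction_touching_no_metabolite_rejected(self, toy1):
        doc = model_to_dict(toy1)
        doc["reactions"].append({"id": "EMPTY", "stoichiometry": {},
                                 "rev": 0, "lb": 0, "ub": 1, "gpr": []})
        with pytest.raises(ValidationError, match="no metabolite"):
            model_from_dict(doc)

    def test_base_names_strip_compartment(self, toy1):
        assert toy1.base_metabolite_of["A[e]"] == "A"
        assert toy1.base_metabolite_of["A[c]"] == "A"
        assert toy1.base_metabolite_of["biomass[c]"] == "biomass"

    def test_substrate_reactions_pools_compartments(self, toy1):
        # A[e] consumed by T1 and by the reversible exchange; A[c] by R2, R3
        assert toy1.substrate_reactions("A") == {"EX_A", "T1", "R2", "R3"}
        # biomass is consumed only by the growth sink
        assert toy1.substrate_reactions("biomass") == {"GROWTH"}


class TestIO:
    def test_json_roundtrip(self, toy1, tmp_path):
        path = tmp_path / "m.json"
        write_model(toy1, path)
        back = load_model(path, format="json")
        assert model_to_dict(back) == model_to_dict(toy1)

    def test_parse_failure_reports_position(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{broken")
        with pytest.raises(FormatError, match="line"):
            load_model(path, format="json")

    def test_tsv_dialect(self, tmp_path):
        d = tmp_path
        (d / "metabolites.tsv").write_text(
            "id\tcurrency\nA[e]\t0\nA[c]\t0\n")
        (d / "reactions.tsv").write_text(
            "id\trev\tlb\tub\tgpr\tobjective\n"
            "EX_A\t1\t-10\t1000\t\t0\n"
            "T\t0\t0\t1000\tg1|g2&g3\t0\n"
            "GROW\t0\t0\t1000\t\t1\n")
        (d / "stoichiometry.tsv").write_text(
            "reaction\tmetabolite\tcoefficient\n"
            "EX_A\tA[e]\t-1\nT\tA[e]\t-1\nT\tA[c]\t1\n"
            "GROW\tA[c]\t-1\n")
        model = load_model(d, format="tsv")
        assert model.objective_id == "GROW"
        assert model.gpr["T"] == [frozenset({"g1"}), frozenset({"g2", "g3"})]
        assert fba(model, "GROW").objective_value == pytest.approx(10.0)

    def test_sbml_not_supported(self, tmp_path):
        with pytest.raises(FormatError, match="SBML"):
            load_model(tmp_path / "x.xml", format="sbml")

    def test_task_file_roundtrip(self, tmp_path, toy1):
        path = tmp_path / "tasks.json"
        write_tasks(toy_tasks(toy1), path)
        tasks = load_tasks(path)
        assert tasks[0].task_id == "biomass_from_source"
        assert tasks[0].allowed_inputs == {"A[e]": 10.0}

    def test_task_without_outputs_rejected(self):
        with pytest.raises(ValidationError, match="required outputs"):
            MetabolicTask("t", {}, {})


class TestFBA:
    def test_toy1_growth_optimum(self, toy1):
        res = fba(toy1, "GROWTH")
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(5.0)

    def test_toy1_atp_consumption_optimum(self, toy1):
        assert fba(toy1, "ATPase").objective_value == pytest.approx(5.0)

    def test_closed_exchanges_force_zero_growth(self, toy1):
        closed = delete_reactions(toy1, ["EX_A"])
        assert fba(closed, "GROWTH").objective_value == pytest.approx(0.0)

    def test_removing_biomass_reaction_zeroes_growth(self, toy1):
        assert fba(delete_reactions(toy1, ["R4"]),
                   "GROWTH").objective_value == pytest.approx(0.0)

    def test_infeasible_status(self, toy1):
        model = toy1.copy()
        model.lb[model.reaction_index("GROWTH")] = 1.0  # demand growth
        model.lb[model.reaction_index("EX_A")] = 0.0    # without any carbon
        res = fba(model, "GROWTH")
        assert res.status == "infeasible"
        assert res.objective_value is None

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_optimum_matches_independent_assembly(self, seed):
        model = generate_toy_gem("randomized", seed=seed)
        mine = fba(model, "GROWTH").objective_value
        theirs = oracle_max_flux(model, "GROWTH")
        assert mine == pytest.approx(theirs, abs=1e-7)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mass_balance_and_bounds_of_optimum(self, seed):
        model = generate_toy_gem("randomized", seed=seed)
        res = fba(model, "GROWTH")
        assert res.status == "optimal"
        residual = np.abs(model.S @ res.fluxes).max()
        assert residual <= 1e-9 * (1 + np.abs(res.fluxes).max())
        assert np.all(res.fluxes >= model.lb - 1e-9)
        assert np.all(res.fluxes <= model.ub + 1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_tightening_bounds_never_raises_optimum(self, seed):
        rng = np.random.default_rng(seed)
        model = generate_toy_gem("randomized", seed=seed)
        base = fba(model, "GROWTH").objective_value
        j = int(rng.integers(model.n_reactions))
        tightened = model.copy()
        tightened.ub[j] *= rng.uniform(0, 1)
        if tightened.ub[j] < tightened.lb[j]:
            tightened.lb[j] = tightened.ub[j]
        res = fba(tightened, "GROWTH")
        assert res.status != "optimal" or res.objective_value <= base + 1e-7


class TestDeletion:
    def test_deletion_closes_bounds_and_preserves_structure(self, toy1):
        out = delete_reactions(toy1, ["R2"])
        j = out.reaction_index("R2")
        assert (out.lb[j], out.ub[j]) == (0.0, 0.0)
        assert out.reaction_ids == toy1.reaction_ids
        assert toy1.ub[toy1.reaction_index("R2")] > 0  # original untouched

    def test_empty_deletion_is_identity(self, toy1):
        assert fba(delete_reactions(toy1, []), "GROWTH").objective_value == \
            pytest.approx(fba(toy1, "GROWTH").objective_value)

    def test_union_equals_sequential_deletion(self, toy1):
        joint = delete_reactions(toy1, ["R2", "R3"])
        seq = delete_reactions(delete_reactions(toy1, ["R2"]), ["R3"])
        assert fba(joint, "GROWTH").objective_value == \
            pytest.approx(fba(seq, "GROWTH").objective_value)

    def test_unknown_reaction_rejected(self, toy1):
        with pytest.raises(ValidationError, match="unknown reaction"):
            delete_reactions(toy1, ["nope"])

    def test_deleting_everything_zeroes_growth(self, toy1):
        dead = delete_reactions(toy1, toy1.reaction_ids)
        assert fba(dead, "GROWTH").objective_value == pytest.approx(0.0)


class TestTasks:
    def test_biomass_task_feasible_on_intact_model(self, toy1):
        assert check_task(toy1, toy_tasks(toy1)[0]) is True

    def test_task_fails_after_deleting_sole_route(self, toy1):
        broken = delete_reactions(toy1, ["R2"])
        assert check_task(broken, toy_tasks(toy1)[0]) is False

    def test_task_without_inputs_is_blocked(self, toy1):
        task = MetabolicTask("no_input", {}, {"biomass[c]": 0.1})
        assert check_task(toy1, task) is False

    def test_unresolvable_metabolite_rejected(self, toy1):
        task = MetabolicTask("bad", {"ghost[c]": 1.0}, {"biomass[c]": 0.1})
        with pytest.raises(ValidationError, match="unknown metabolite"):
            check_task(toy1, task)

    def test_check_task_restores_model(self, toy1):
        lb, ub = toy1.lb.copy(), toy1.ub.copy()
        check_task(toy1, toy_tasks(toy1)[0])
        assert np.array_equal(toy1.lb, lb) and np.array_equal(toy1.ub, ub)


class TestViability:
    def test_intact_model_viable(self, toy1):
        assert is_viable(toy1, tasks=toy_tasks(toy1)) is True

    def test_deleting_biomass_assembly_kills_viability(self, toy1):
        assert is_viable(delete_reactions(toy1, ["R4"]),
                         tasks=toy_tasks(toy1)) is False

    def test_threshold_dominates(self, toy1):
        assert is_viable(toy1, eps=100.0) is False

    def test_nonpositive_eps_rejected(self, toy1):
        with pytest.raises(ValidationError):
            is_viable(toy1, eps=0.0)
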