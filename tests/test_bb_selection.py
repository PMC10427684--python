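"""Building-block selection funnel, validation classification and ranking."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import DataStructs

from delforge.bb_selection import (
    DEFAULT_EXCLUSION_FGS,
    SelectionConfig,
    ValidationError,
    ValidationRecord,
    apply_cutoffs,
    apply_exclusion_filters,
    classify_validation,
    compute_descriptors,
    diversity_pick,
    enumerate_dummy,
    filter_target_fg,
    morgan_fingerprints,
    preference_tier,
    rank_building_blocks,
    run_funnel,
)
from delforge.chem_core import MoleculeRef


def refs(*smiles):
    return [MoleculeRef(smiles=s, origin_id=f"m{i}") for i, s in enumerate(smiles)]


class TestFilters:
    def test_primary_amine_filter(self):
        kept = filter_target_fg(refs("Nc1ccccc1", "CNc1ccccc1"), "[#7;h2]")
        assert [e.smiles for e in kept] == ["Nc1ccccc1"]

    def test_empty_input(self):
        assert filter_target_fg([], "[#7;h2]") == []

    def test_hand_counted_catalog(self):
        # the query is deliberately broad: any N with two hydrogens matches,
        # so the primary amide counts alongside the four primary amines
        catalog = refs(
            "CCN", "NCC1CC1", "Nc1ccccc1", "NCCc1ccccc1", "CC(=O)N",
            "CNC", "CN(C)C", "c1ccncc1", "CCO", "C1CCNC1",
        )
        assert len(filter_target_fg(catalog, "[#7;h2]")) == 5

    @pytest.mark.parametrize(
        "smiles,fg",
        [("NCCS", "thiol"), ("NCC(=O)O", "carboxylic_acid")],
    )
    def test_exclusion_removes(self, smiles, fg):
        out = apply_exclusion_filters(refs(smiles), {fg: DEFAULT_EXCLUSION_FGS[fg]})
        assert out == []

    def test_clean_amine_survives_full_list(self):
        out = apply_exclusion_filters(refs("CCN"), DEFAULT_EXCLUSION_FGS)
        assert [e.smiles for e in out] == ["CCN"]

    def test_order_independent(self):
        entries = refs("NCCS", "CCN", "NCC(=O)O")
        fwd = apply_exclusion_filters(entries, DEFAULT_EXCLUSION_FGS)
        rev = apply_exclusion_filters(entries, dict(reversed(DEFAULT_EXCLUSION_FGS.items())))
        assert [e.smiles for e in fwd] == [e.smiles for e in rev] == ["CCN"]


class TestDummyEnumeration:
    def test_single_product_per_entry(self, reactions):
        products, failed = enumerate_dummy(refs("CCN"), reactions["primary_amine_dummy"])
        assert failed == []
        assert len(products) == 1
        assert products[0].origin_id == "m0"
        # the fixed scaffold is appended: product is much larger than the BB
        from delforge.chem_core import mol_from_smiles

        assert mol_from_smiles(products[0].smiles).GetNumHeavyAtoms() > 25

    def test_nonmatching_entry_recorded_as_failure(self, reactions):
        products, failed = enumerate_dummy(refs("CNC"), reactions["primary_amine_dummy"])
        assert products == []
        assert failed == ["m0"]

    def test_empty_input(self, reactions):
        assert enumerate_dummy([], reactions["primary_amine_dummy"]) == ([], [])


class TestDescriptorsAndCutoffs:
    def test_reference_values(self):
        table = compute_descriptors(refs("C", "O", "CCO"))
        methane, water, ethanol = table.iloc[0], table.iloc[1], table.iloc[2]
        assert methane["HBD"] == 0 and methane["HBA"] == 0 and methane["fsp3"] == 1.0
        assert water["HBD"] == 2
        assert abs(ethanol["exactMW"] - 46.0419) < 1e-3

    @pytest.mark.parametrize(
        "slogp,mw,included",
        [(6.0, 400.0, False), (5.9, 599.9, True), (2.0, 600.0, False)],
    )
    def test_strict_cutoffs(self, slogp, mw, included):
        import pandas as pd

        table = pd.DataFrame({"SLogP": [slogp], "exactMW": [mw]})
        out = apply_cutoffs(table, slogp_max=6.0, mw_max=600.0)
        assert (len(out) == 1) is included


class TestDiversityPick:
    def test_identical_molecules_zero_gain(self):
        entries = refs("CCN", "CCN", "CCN")
        picks = diversity_pick(entries, 1, seed=3)
        assert len(picks) == 1

    def test_outlier_always_picked(self):
        # brute force over all 2-subsets maximizing the min pairwise distance
        entries = refs("CCCCCC", "CCCCCCC", "CCCCC", "c1ccc2ccccc2c1")
        fps = morgan_fingerprints([e.smiles for e in entries])

        def mindist(subset):
            return min(
                1 - DataStructs.TanimotoSimilarity(fps[i], fps[j])
                for i, j in itertools.combinations(subset, 2)
            )

        best = max(itertools.combinations(range(len(entries)), 2), key=mindist)
        assert 3 in best  # the naphthalene outlier is in the brute-force optimum
        for seed in (0, 1, 2):
            picks = diversity_pick(entries, 2, seed=seed)
            assert entries[3] in picks

    def test_oversized_request_returns_all(self):
        entries = refs("CCN", "CCO")
        assert diversity_pick(entries, 5, seed=0) == entries

    def test_deterministic_given_seed(self):
        entries = refs("CCN", "CCCN", "Nc1ccccc1", "NC1CC1", "NCCO", "NCCCO")
        a = diversity_pick(entries, 3, seed=11)
        b = diversity_pick(entries, 3, seed=11)
        assert a == b

    def test_avoid_set_biases_away(self):
        entries = refs("CCN", "CCCN", "Nc1ccccc1")
        avoid = refs("CCN")
        picks = diversity_pick(entries, 1, seed=0, avoid=avoid)
        assert picks[0].smiles != "CCN"


class TestValidationClassification:
    @pytest.mark.parametrize(
        "product,unknown,expected",
        [(75, 5, True), (78, 11, False), (70, 5, False), (71, 10, False)],
    )
    def test_inclusion_rule(self, product, unknown, expected):
        assert classify_validation(product, unknown) is expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            classify_validation(105.0, 5.0)

    @given(
        product=st.floats(min_value=0, max_value=100),
        unknown=st.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_record_consistent_with_rule(self, product, unknown):
        rec = ValidationRecord(
            bb_id="b", reaction_class="acylation",
            pct_auc_product=product, pct_auc_unknown=unknown,
        )
        assert rec.included == (product > 70 and unknown < 10)


class TestRanking:
    def make(self, pairs):
        return [
            ValidationRecord("b%d" % i, "acylation", p, u)
            for i, (p, u) in enumerate(pairs)
        ]

    def test_two_phase_order(self):
        ranked = rank_building_blocks(self.make([(90, 2), (80, 15), (85, 9)]))
        assert [(r.pct_auc_product, r.pct_auc_unknown) for r in ranked] == [
            (90, 2), (85, 9), (80, 15),
        ]

    def test_all_high_unknowns_pure_descending(self):
        ranked = rank_building_blocks(self.make([(50, 20), (90, 30), (70, 15)]))
        assert [r.pct_auc_product for r in ranked] == [90, 70, 50]

    def test_comparator_on_all_permutations(self):
        # exhaustive check of the stated comparator over permutations of 4 records
        base = [(80, 5), (80, 9), (80, 15), (60, 2)]
        expected = [(80, 5), (80, 9), (60, 2), (80, 15)]
        for perm in itertools.permutations(base):
            ranked = rank_building_blocks(self.make(list(perm)))
            assert [
                (r.pct_auc_product, r.pct_auc_unknown) for r in ranked
            ] == expected


class TestPreferenceTier:
    @pytest.mark.parametrize(
        "inc_i,inc_br,p_i,p_br,tier",
        [
            (True, True, 90, 90, 4),
            (True, False, 90, 75, 3),
            (False, True, 72, 90, 3),
            (True, False, 90, 50, 2),
            (False, False, 50, 50, 1),
        ],
    )
    def test_tiers(self, inc_i, inc_br, p_i, p_br, tier):
        assert preference_tier(inc_i, inc_br, p_i, p_br) == tier


class TestFunnel:
    def test_monotone_and_deterministic(self, reactions):
        catalog = refs(
            "CCN", "CCCN", "Nc1ccccc1", "CNC", "NCCS", "NCC(=O)O",
            "NC1CCCCC1", "CCOC", "NCCc1ccccc1", "NC(C)C",
        )
        config = SelectionConfig(
            dummy_template=reactions["primary_amine_dummy"],
            round1_pick=3, round2_pick=2, seed=5,
        )
        picks1, report1 = run_funnel(catalog, config)
        picks2, report2 = run_funnel(catalog, config)
        assert [p.origin_id for p in picks1] == [p.origin_id for p in picks2]
        assert report1.equals(report2)
        counts = report1["count"].tolist()
        funnel_stages = counts[:5]  # input .. round1_cutoffs shrink monotonically
        assert all(a >= b for a, b in zip(funnel_stages, funnel_stages[1:]))

    def test_round2_cutoffs_must_be_tighter(self):
        with pytest.raises(ValueError):
            SelectionConfig(round2_slogp_max=7.0)
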