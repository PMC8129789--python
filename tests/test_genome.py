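"""Tests for MEROPS filtering/tabulation, set algebra, and KEGG module MCRs."""

import io
import itertools
import re

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoprobe import genome, synthetic
from thermoprobe.genome import MeropsHit, ModuleParseError


# --------------------------------------------------------------------------
# Independent MCR oracle: translate each step into a Python boolean
# expression over KO membership and eval it. Shares no code with the parser.
# --------------------------------------------------------------------------

def oracle_mcr(definition: str, kos: set[str]) -> float:
    """Truth-table oracle for module completion.

    Splits top-level space-separated steps by paren depth, then rewrites each
    step as a Python expression: KO -> membership test, ',' -> or, '+' and
    inner spaces -> and, '-X' -> True (optional), '--' -> False (gap step).
    """
    steps, depth, cur = [], 0, ""
    for ch in definition.strip():
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == " " and depth == 0:
            steps.append(cur)
            cur = ""
        else:
            cur += ch
    steps.append(cur)
    # wholly optional steps are ignored for completion
    steps = [s for s in steps if not (s.startswith("-") and not s.startswith("--"))]

    def step_expr(step: str) -> str:
        step = step.replace("--", " False ")
        # optional members: -K123 or -( ... ) contribute True
        step = re.sub(r"-K(\d+)", " True ", step)
        step = re.sub(r"K(\d+)", lambda m: str(f"K{m.group(1)}" in kos), step)
        step = step.replace(",", " or ").replace("+", " and ")
        # remaining spaces inside a step are ANDs between juxtaposed groups
        step = re.sub(r"(?<=[)el])\s+(?=[(TF])", " and ", step)
        return step

    sat = sum(bool(eval(step_expr(s))) for s in steps)
    return sat / len(steps)


SYNTHETIC_MODULES = [
    "K00001",
    "K00001 K00002",
    "K00001 (K00002,K00003)",
    "(K00001,K00002) (K00003,K00004) K00005",
    "K00001+K00002 K00003",
    "K00001+K00002+K00003",
    "(K00001+K00002,K00003) K00004",
    "K00001 -K00002 K00003",
    "K00001 -- K00003",
    "((K00001,K00002) K00003,K00004)",
    "K00001 (K00002+K00003,K00004) (K00005,K00006) K00007",
    "(K00001,K00002+K00003) -K00004 K00005 (K00006,K00007,K00008)",
]


class TestModuleParsing:
    def test_single_ko_single_step(self):
        m = genome.parse_module_definition("K00001")
        assert m.n_steps == 1
        assert genome.step_satisfied(m.steps[0], {"K00001"})

    def test_two_steps_with_alternatives(self):
        m = genome.parse_module_definition("K00001 (K00002,K00003)")
        assert m.n_steps == 2
        assert genome.step_satisfied(m.steps[1], {"K00003"})
        assert not genome.step_satisfied(m.steps[1], {"K00009"})

    def test_unbalanced_parenthesis_rejected(self):
        with pytest.raises(ModuleParseError):
            genome.parse_module_definition("K00001 (K00002")

    def test_empty_definition_rejected(self):
        with pytest.raises(ModuleParseError):
            genome.parse_module_definition("   ")

    def test_complex_members_all_required(self):
        m = genome.parse_module_definition("K00001+K00002")
        assert not genome.step_satisfied(m.steps[0], {"K00001"})
        assert genome.step_satisfied(m.steps[0], {"K00001", "K00002"})

    def test_optional_member_ignored(self):
        m = genome.parse_module_definition("K00001-K00002")
        assert genome.step_satisfied(m.steps[0], {"K00001"})

    def test_gap_step_never_satisfied(self):
        m = genome.parse_module_definition("K00001 -- K00003")
        assert genome.module_completion_ratio(m, {"K00001", "K00003"}).mcr == pytest.approx(2 / 3)


class TestMCR:
    def test_full_ko_set_gives_one(self):
        for d in SYNTHETIC_MODULES:
            if "--" in d:
                continue
            m = genome.parse_module_definition(d)
            assert genome.module_completion_ratio(m, genome.module_kos(m)).mcr == 1.0

    def test_empty_ko_set_gives_zero(self):
        for d in SYNTHETIC_MODULES:
            m = genome.parse_module_definition(d)
            assert genome.module_completion_ratio(m, set()).mcr == 0.0

    def test_or_step_half_example(self):
        m = genome.parse_module_definition("K00001 (K00002,K00003)")
        assert genome.module_completion_ratio(m, {"K00002"}).mcr == 0.5

    @pytest.mark.parametrize("definition", SYNTHETIC_MODULES)
    def test_matches_truth_table_oracle_on_all_subsets(self, definition):
        m = genome.parse_module_definition(definition)
        kos = sorted(genome.module_kos(m))
        assert len(kos) <= 12
        for bits in itertools.product([0, 1], repeat=len(kos)):
            subset = {k for k, b in zip(kos, bits) if b}
            ours = genome.module_completion_ratio(m, subset).mcr
            assert ours == pytest.approx(oracle_mcr(definition, subset)), (
                definition, subset,
            )

    @settings(derandomize=True, max_examples=60)
    @given(
        st.integers(min_value=0, max_value=len(SYNTHETIC_MODULES) - 1),
        st.sets(st.sampled_from([f"K0000{i}" for i in range(1, 9)])),
        st.sampled_from([f"K0000{i}" for i in range(1, 9)]),
    )
    def test_mcr_monotone_under_ko_growth(self, idx, subset, extra):
        m = genome.parse_module_definition(SYNTHETIC_MODULES[idx])
        base = genome.module_completion_ratio(m, subset).mcr
        grown = genome.module_completion_ratio(m, subset | {extra}).mcr
        assert grown >= base


class TestFeasibility:
    def test_low_q_feasible(self):
        r = genome.McrResult("M1", 1.0)
        assert genome.feasibility_call(r, 0.3).feasible is True

    def test_q_exactly_half_not_feasible(self):
        r = genome.McrResult("M1", 1.0)
        assert genome.feasibility_call(r, 0.5).feasible is False

    def test_missing_q_unknown(self):
        r = genome.McrResult("M1", 1.0)
        assert genome.feasibility_call(r, None).feasible is None

    def test_q_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            genome.feasibility_call(genome.McrResult("M1", 1.0), 1.5)


class TestMeropsFiltering:
    def test_e_value_cutoff(self):
        hits = [
            MeropsHit("g1", "S01C", 1e-12, 80.0),
            MeropsHit("g2", "M20", 1e-9, 90.0),
        ]
        kept = genome.filter_merops_hits(hits)
        assert [h.query_gene for h in kept] == ["g1"]

    def test_empty_input(self):
        assert genome.filter_merops_hits([]) == []

    def test_best_hit_by_bit_score(self):
        hits = [
            MeropsHit("g1", "S01C", 1e-12, 60.0),
            MeropsHit("g1", "M20", 1e-12, 80.0),
        ]
        kept = genome.filter_merops_hits(hits)
        assert len(kept) == 1 and kept[0].family == "M20"

    def test_tie_breaks_deterministic(self):
        hits = [
            MeropsHit("g1", "S08A", 1e-12, 80.0),
            MeropsHit("g1", "M20", 1e-12, 80.0),
        ]
        kept = genome.filter_merops_hits(hits)
        assert kept[0].family == "M20"  # lexicographically smallest on full tie

    def test_filter_is_idempotent(self):
        hits = [
            MeropsHit("g1", "S01C", 1e-12, 60.0),
            MeropsHit("g1", "M20", 1e-15, 80.0),
            MeropsHit("g2", "C26", 1e-11, 50.0),
            MeropsHit("g3", "M28F", 1e-9, 99.0),
        ]
        once = genome.filter_merops_hits(hits)
        twice = genome.filter_merops_hits(once)
        assert once == twice

    def test_blast_tab_parsing_and_malformed_row(self):
        good = "gene1\tMER0001_S01C\t45.2\t100\t20\t1\t1\t100\t5\t104\t1e-20\t85.3\n"
        hits = genome.read_blast_tab(io.StringIO(good))
        assert hits[0].family == "S01C" and hits[0].e_value == 1e-20
        bad = "gene1\tMER0001_S01C\t45.2\n"
        with pytest.raises(ValueError, match="line 1"):
            genome.read_blast_tab(io.StringIO(bad))


class TestTabulation:
    def test_empty_annotation_zero_profile(self):
        df = pd.DataFrame({"gene_id": ["g1"], "family": [""], "locality": ["cytoplasmic"]})
        prof = genome.tabulate_families(df, total_genes=10)
        assert prof.peptidase_gene_count == 0

    def test_planted_counts_recovered(self):
        table = synthetic.generate_annotation_table(
            100, {"S01C": 7, "M20": 8}, seed=5
        )
        prof = genome.tabulate_families(table, total_genes=100)
        assert prof.counts == {"S01C": 7, "M20": 8}

    def test_clan_totals(self):
        counts = {"M20": 25, "M28F": 26, "S01C": 30, "S08A": 23}
        prof = genome.FamilyProfile("g", counts, 3000)
        assert prof.clan_totals() == {"M": 51, "S": 53}

    def test_duplicate_gene_id_rejected(self):
        df = pd.DataFrame(
            {"gene_id": ["g1", "g1"], "family": ["S01C", "M20"],
             "locality": ["cytoplasmic"] * 2}
        )
        with pytest.raises(ValueError, match="duplicate"):
            genome.tabulate_families(df, total_genes=10)


class TestPercentages:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(133, 2997, 4.44), (0, 2997, 0.00), (52, 133, 39.10), (56, 133, 42.11)],
    )
    def test_peptidase_percentage(self, count, total, expected):
        assert genome.peptidase_percentage(count, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            genome.peptidase_percentage(1, 0)

    def test_genome_table_percentages(self):
        st_ = genome.annotation_stats(3216964, 2875571, 2166171, 2997, 2944)
        assert st_.coding_pct == 89.39
        assert st_.gc_pct == 67.34
        assert st_.protein_coding_pct == 98.23

    def test_part_exceeding_whole_rejected(self):
        with pytest.raises(ValueError):
            genome.annotation_stats(100, 150, 10, 10, 5)


class TestSharedFamilies:
    @staticmethod
    def _profile(gid, families):
        return genome.FamilyProfile(gid, {f: 1 for f in families}, 1000)

    def test_identical_sets(self):
        p1 = self._profile("a", {"S01C", "M20"})
        p2 = self._profile("b", {"S01C", "M20"})
        rep = genome.shared_families([p1, p2])
        assert rep["intersection"] == rep["union"] == frozenset({"S01C", "M20"})
        assert all(not u for u in rep["unique"].values())

    def test_disjoint_sets(self):
        p1 = self._profile("a", {"S01C"})
        p2 = self._profile("b", {"M20"})
        rep = genome.shared_families([p1, p2])
        assert rep["intersection"] == frozenset()
        assert rep["unique"]["a"] == frozenset({"S01C"})

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(ValueError):
            genome.shared_families([self._profile("a", {"S01C"})])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(
        st.sets(st.sampled_from(["A1", "C26", "M20", "M38", "S01C", "S08A", "S33"])),
        min_size=2, max_size=5,
    ))
    def test_venn_partition_matches_brute_force(self, sets):
        profiles = [self._profile(f"g{i}", s) for i, s in enumerate(sets)]
        rep = genome.shared_families(profiles)
        # brute force: each family of the union lands in exactly one cell
        cells = rep["venn"]
        all_cell_families = [f for cell in cells.values() for f in cell]
        assert len(all_cell_families) == len(set(all_cell_families))
        assert set(all_cell_families) == set(rep["union"])
        for members, cell in cells.items():
            for fam in cell:
                expect = tuple(
                    sorted(p.genome_id for p in profiles if fam in p.families_present)
                )
                assert expect == members


class TestPercentileRank:
    def test_max_of_unique_reference(self):
        ref = list(range(100))
        assert genome.percentile_rank(99, ref) == 1.0

    def test_min_of_reference(self):
        ref = list(range(100))
        assert genome.percentile_rank(0, ref) == 100.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            genome.percentile_rank(1.0, [])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=60),
        st.integers(min_value=0, max_value=50),
    )
    def test_matches_brute_force_count(self, ref, value):
        expected = 100.0 * len([r for r in ref if r >= value]) / len(ref)
        assert genome.percentile_rank(value, ref) == expected
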