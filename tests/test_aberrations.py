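import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icpipe import count_aberrations, pathway_aberration_counts, recurrence_table
from icpipe.types import (
    GAIN,
    LOSS,
    NEUTRAL,
    CopyNumberCalls,
    DegenerateInputError,
    GeneSetCollection,
)


def build_calls(n_gain, n_loss, n_loh_only, n_neutral=5, sample="s1"):
    """Single-sample call matrix with given per-type counts (LOH on its own
    copy-neutral genes)."""
    states = [GAIN] * n_gain + [LOSS] * n_loss + [NEUTRAL] * (n_loh_only + n_neutral)
    loh = [False] * (n_gain + n_loss) + [True] * n_loh_only + [False] * n_neutral
    genes = [f"g{i:05d}" for i in range(len(states))]
    return CopyNumberCalls(
        pd.DataFrame({sample: states}, index=genes),
        pd.DataFrame({sample: loh}, index=genes),
    )


class TestBurden:
    def test_low_burden_sample_totals(self):
        # 1 gain + 1582 loss + 141 LOH -> total 1724
        calls = build_calls(1, 1582, 141)
        row = count_aberrations(calls).loc["s1"]
        assert (row["gain"], row["loss"], row["loh"], row["total"]) == (1, 1582, 141, 1724)

    def test_high_burden_sample_totals(self):
        calls = build_calls(7202, 15355, 74)
        row = count_aberrations(calls).loc["s1"]
        assert row["total"] == 22631

    def test_all_neutral_zero(self):
        calls = build_calls(0, 0, 0, n_neutral=10)
        assert (count_aberrations(calls).to_numpy() == 0).all()

    def test_loss_plus_loh_counts_in_both(self):
        state = pd.DataFrame({"s1": [LOSS]}, index=["g1"])
        loh = pd.DataFrame({"s1": [True]}, index=["g1"])
        row = count_aberrations(CopyNumberCalls(state, loh)).loc["s1"]
        assert (row["loss"], row["loh"], row["total"]) == (1, 1, 2)

    def test_gene_subset_restriction(self):
        calls = build_calls(3, 2, 1)
        subset = calls.genes[:3]  # the three GAIN genes
        row = count_aberrations(calls, subset).loc["s1"]
        assert (row["gain"], row["total"]) == (3, 3)

    def test_empty_subset_error(self):
        calls = build_calls(1, 1, 1)
        with pytest.raises(DegenerateInputError):
            count_aberrations(calls, ["absent_gene"])

    @given(split=st.integers(min_value=1, max_value=9), data=st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_partition_additivity(self, split, data):
        """Burden counts over a gene partition sum to the genome-wide counts."""
        rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
        genes = [f"g{i}" for i in range(10)]
        state = pd.DataFrame(
            rng.choice([LOSS, NEUTRAL, GAIN], size=(10, 4)),
            index=genes, columns=list("abcd"),
        )
        loh = pd.DataFrame(rng.random((10, 4)) < 0.3, index=genes, columns=list("abcd"))
        calls = CopyNumberCalls(state, loh)
        total = count_aberrations(calls)
        part1 = count_aberrations(calls, genes[:split])
        part2 = count_aberrations(calls, genes[split:])
        pd.testing.assert_frame_equal(part1 + part2, total)
        # restriction monotonicity
        assert (part1.to_numpy() <= total.to_numpy()).all()


class TestRecurrence:
    def _cohort_with_recurrent_gene(self, gene, aberration, n_carriers, n_samples=18):
        samples = [f"cl{i:02d}" for i in range(n_samples)]
        state = pd.DataFrame(NEUTRAL, index=[gene, "other"], columns=samples)
        loh = pd.DataFrame(False, index=[gene, "other"], columns=samples)
        if aberration == "LOH":
            loh.loc[gene, samples[:n_carriers]] = True
        else:
            state.loc[gene, samples[:n_carriers]] = GAIN if aberration == "GAIN" else LOSS
        return CopyNumberCalls(state, loh)

    @pytest.mark.parametrize(
        "aberration,n_carriers,expected_pct",
        [("GAIN", 13, 72), ("LOSS", 8, 44), ("LOH", 11, 61), ("LOH", 10, 56)],
    )
    def test_rounded_percent_frequencies(self, aberration, n_carriers, expected_pct):
        calls = self._cohort_with_recurrent_gene("target", aberration, n_carriers)
        tab = recurrence_table(calls, aberration, top_n=1)
        assert tab.iloc[0]["gene"] == "target"
        assert tab.iloc[0]["n_samples"] == n_carriers
        assert tab.iloc[0]["frequency"] == expected_pct

    def test_tie_break_lexicographic(self):
        samples = ["a", "b"]
        state = pd.DataFrame(GAIN, index=["zz", "aa"], columns=samples)
        loh = pd.DataFrame(False, index=["zz", "aa"], columns=samples)
        tab = recurrence_table(CopyNumberCalls(state, loh), "GAIN", top_n=2)
        assert tab["gene"].tolist() == ["aa", "zz"]

    def test_empty_calls_empty_table(self):
        calls = CopyNumberCalls(
            pd.DataFrame(dtype=np.int8, columns=["s1"]),
            pd.DataFrame(dtype=bool, columns=["s1"]),
        )
        assert recurrence_table(calls, "GAIN", top_n=5).empty

    def test_unknown_type_rejected(self, small_calls):
        with pytest.raises(ValueError, match="unknown aberration type"):
            recurrence_table(small_calls, "AMP", top_n=1)


class TestPathwayCounts:
    def test_whole_genome_pathway_equals_burden_sums(self, small_calls):
        gs = GeneSetCollection({"ALL": ("everything", small_calls.genes)})
        tab = pathway_aberration_counts(small_calls, gs, top_n=1)
        burden = count_aberrations(small_calls).sum()
        row = tab.iloc[0]
        assert (row["gain"], row["loss"], row["loh"], row["total"]) == (
            burden["gain"], burden["loss"], burden["loh"], burden["total"],
        )

    def test_disjoint_partition_additivity(self, small_calls):
        gs = GeneSetCollection(
            {"P1": ("", small_calls.genes[:1]), "P2": ("", small_calls.genes[1:])}
        )
        tab = pathway_aberration_counts(small_calls, gs, top_n=2).set_index("pathway")
        burden = count_aberrations(small_calls).sum()
        for col in ("gain", "loss", "loh", "total"):
            assert tab[col].sum() == burden[col]

    def test_hand_built_pathway_matches_enumeration(self, small_calls):
        members = ["g1", "g3"]
        gs = GeneSetCollection({"P": ("", members)})
        tab = pathway_aberration_counts(small_calls, gs, top_n=1).iloc[0]
        # independent brute-force count over all (gene, sample) cells
        expected = {"gain": 0, "loss": 0, "loh": 0}
        for g in members:
            for s in small_calls.samples:
                v = small_calls.state.loc[g, s]
                if v == GAIN:
                    expected["gain"] += 1
                elif v == LOSS:
                    expected["loss"] += 1
                if small_calls.loh.loc[g, s]:
                    expected["loh"] += 1
        assert tab["gain"] == expected["gain"]
        assert tab["loss"] == expected["loss"]
        assert tab["loh"] == expected["loh"]
        assert tab["total"] == sum(expected.values())

    def test_missing_members_count_zero(self, small_calls):
        gs = GeneSetCollection({"P": ("", ["not_in_matrix"])})
        tab = pathway_aberration_counts(small_calls, gs, top_n=1)
        assert tab.iloc[0]["total"] == 0

    def test_per_sample_breakdown_sums_to_aggregate(self, small_calls):
        gs = GeneSetCollection({"P": ("", small_calls.genes)})
        tab, mats = pathway_aberration_counts(small_calls, gs, top_n=1, per_sample=True)
        assert mats["GAIN"].loc["P"].sum() == tab.iloc[0]["gain"]
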