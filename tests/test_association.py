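"""Group splitting, one-sided Fisher, probe scan and permutation p cutoff."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ascn_assoc import (
    AnalysisParams,
    GenotypeTable,
    GroupSplit,
    ProbeManifest,
    RiskVariantSpec,
    fisher_one_sided,
    p_cutoff_by_permutation,
    probe_scan,
    significant_regions,
    split_groups,
)
from ascn_assoc.model import DegenerateSplitError

from conftest import make_matrix


def fisher_enumeration_oracle(a, b, c, d):
    """Upper-tail Fisher p by direct summation of the hypergeometric pmf."""
    n, k, draws = a + b + c + d, a + c, a + b
    total = 0.0
    for x in range(a, min(draws, k) + 1):
        if draws - x > n - k:  # not enough non-events to fill the risk row
            continue
        total += (
            math.comb(k, x) * math.comb(n - k, draws - x) / math.comb(n, draws)
        )
    return total


def genotype_table(labels, variant="rs_test"):
    idx = [f"s{i}" for i in range(len(labels))]
    return GenotypeTable(pd.DataFrame({variant: labels}, index=idx))


def variant(risk_is_major=True, variant_id="rs_test", surrogate=None):
    return RiskVariantSpec(
        variant_id=variant_id,
        chrom="7",
        pos=100,
        gene="G",
        major_allele="G",
        risk_allele="G" if risk_is_major else "A",
        surrogate_id=surrogate,
    )


class TestSplitGroups:
    def test_major_risk_allele(self):
        gt = genotype_table(["major_hom", "major_hom", "het", "rare_hom", "major_hom"])
        split = split_groups(gt, variant(risk_is_major=True))
        assert split.n_risk == 3 and split.n_other == 2
        assert set(split.risk_group) == {"s0", "s1", "s4"}

    def test_rare_risk_allele_takes_carrier_group(self):
        gt = genotype_table(["major_hom", "major_hom", "het", "rare_hom", "major_hom"])
        split = split_groups(gt, variant(risk_is_major=False))
        assert set(split.risk_group) == {"s2", "s3"}
        assert not split.risk_is_major

    def test_missing_genotype_in_neither_group(self):
        gt = genotype_table(["major_hom", np.nan, "het"])
        split = split_groups(gt, variant())
        assert "s1" not in split.risk_group + split.other_group

    def test_degenerate_split_rejected(self):
        gt = genotype_table(["major_hom", "major_hom"])
        with pytest.raises(DegenerateSplitError):
            split_groups(gt, variant())

    def test_surrogate_fallback(self):
        gt = genotype_table(["major_hom", "het"], variant="rs_sur")
        split = split_groups(gt, variant(variant_id="rs_main", surrogate="rs_sur"))
        assert split.variant_id == "rs_main"

    def test_groups_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            GroupSplit("v", ("s1",), ("s1",), True)


# the twelve published 2x2 tables (risk group row first), with printed p
PUBLISHED_TABLES = [
    ("umu_egfr_loh", 19, 41, 2, 19, 0.0385),
    ("umu_cdkn2a_hd", 33, 24, 8, 16, 0.0374),
    ("umu_cdkn2b_hd_v1", 32, 25, 7, 17, 0.0233),
    ("umu_cdkn2b_hd_v2", 34, 26, 5, 16, 0.0088),
    ("umu_mtap_cdkn2a", 35, 25, 5, 16, 0.0062),
    ("umu_mtap_cdkn2bas", 33, 27, 4, 17, 0.0040),
    ("tcga_egfr_loh", 57, 179, 6, 43, 0.0455),
    ("tcga_cdkn2a_hd", 51, 158, 10, 66, 0.0267),
    ("tcga_cdkn2b_hd_v1", 122, 87, 32, 44, 0.0107),
    ("tcga_cdkn2b_hd_v2", 134, 102, 20, 29, 0.0300),
    ("tcga_mtap_cdkn2a", 135, 101, 20, 29, 0.0264),
    ("tcga_mtap_cdkn2bas", 132, 104, 19, 30, 0.0210),
]


class TestFisherOneSided:
    @pytest.mark.parametrize(
        "label,a,b,c,d,expected", PUBLISHED_TABLES, ids=[t[0] for t in PUBLISHED_TABLES]
    )
    def test_published_tables_to_four_decimals(self, label, a, b, c, d, expected):
        assert round(fisher_one_sided(a, b, c, d), 4) == expected

    def test_zero_events_gives_one(self):
        for b, d in [(1, 1), (5, 9), (0, 3)]:
            assert fisher_one_sided(0, b, 0, d) == 1.0

    def test_two_by_two_closed_form(self):
        assert fisher_one_sided(2, 0, 0, 2) == pytest.approx(1 / 6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 2, 3, 4)

    @given(
        st.tuples(
            st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
        )
    )
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        assert fisher_one_sided(a, b, c, d) == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )

    @given(
        st.tuples(
            st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10)
        ).filter(lambda t: sum(t) > 0)
    )
    def test_group_relabel_symmetry(self, table):
        """Swapping the groups flips the tail: p(a,b,c,d) + p(c,d,a,b)
        = 1 + P(X = a), the shared boundary term."""
        a, b, c, d = table
        p_risk = fisher_one_sided(a, b, c, d)
        p_swap = fisher_one_sided(c, d, a, b)
        n, k, draws = a + b + c + d, a + c, a + b
        lo = max(0, draws - (n - k))
        point = (
            math.comb(k, a) * math.comb(n - k, b) / math.comb(n, draws)
            if lo <= a <= min(draws, k)
            else 0.0
        )
        assert p_risk + p_swap == pytest.approx(1.0 + point, abs=1e-9)


def sixty_twentyone_matrix(n_risk_event=19, n_other_event=2, extra_probe=None):
    """One informative probe over 60 risk + 21 other samples."""
    risk = [f"r{i}" for i in range(60)]
    other = [f"o{i}" for i in range(21)]
    col = [1.0] * n_risk_event + [0.0] * (60 - n_risk_event)
    col += [1.0] * n_other_event + [0.0] * (21 - n_other_event)
    cols = {"prA": col}
    if extra_probe is not None:
        cols["prB"] = extra_probe
    df = pd.DataFrame(cols, index=risk + other)
    from ascn_assoc import EventMatrix, EventType

    return (
        EventMatrix(EventType.LOH, df),
        GroupSplit("rs_test", tuple(risk), tuple(other), True),
    )


class TestProbeScan:
    def _manifest(self, n):
        return ProbeManifest.from_arrays(
            [f"pr{c}" for c in "AB"[:n]], ["1"] * n, [100, 200][:n]
        )

    def test_published_counts_give_published_p(self):
        matrix, split = sixty_twentyone_matrix()
        scan = probe_scan(matrix, split, cutoff=0.2, manifest=self._manifest(1))
        assert round(scan["p"].iloc[0], 4) == 0.0385
        assert (scan[["a", "b", "c", "d"]].iloc[0] == [19, 41, 2, 19]).all()

    def test_probe_below_cutoff_has_missing_p(self):
        matrix, split = sixty_twentyone_matrix(extra_probe=[0.0] * 81)
        scan = probe_scan(matrix, split, cutoff=0.2, manifest=self._manifest(2))
        assert not scan["masked"].iloc[1]
        assert np.isnan(scan["p"].iloc[1])

    def test_equal_group_frequencies_not_significant(self):
        matrix, split = sixty_twentyone_matrix(n_risk_event=20, n_other_event=7)
        scan = probe_scan(matrix, split, cutoff=0.1, manifest=self._manifest(1))
        assert scan["p"].iloc[0] >= 0.5

    def test_empty_mask_warns(self):
        matrix, split = sixty_twentyone_matrix(n_risk_event=0, n_other_event=0)
        with pytest.warns(UserWarning, match="no probe exceeds"):
            scan = probe_scan(matrix, split, cutoff=0.5, manifest=self._manifest(1))
        assert scan["p"].isna().all()


class TestPCutoffByPermutation:
    def test_no_events_anywhere_gives_one(self):
        matrix, split = sixty_twentyone_matrix(n_risk_event=0, n_other_event=0)
        assert p_cutoff_by_permutation(matrix, split, cutoff=0.0, rng=1) == 1.0

    def test_matches_exhaustive_label_enumeration(self):
        """8 samples (4 vs 4), one probe with 3 events: enumerate all 70
        assignments, apply the identical mask+min-p rule, and compare the
        5% lower quantile of the minima (the level at which 95% of null
        assignments stay above) to the sampled permutation estimate."""
        from ascn_assoc import EventMatrix, EventType

        events = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        ids = [f"s{i}" for i in range(8)]
        matrix = EventMatrix(EventType.HD, pd.DataFrame({"prA": events}, index=ids))
        split = GroupSplit("v", tuple(ids[:4]), tuple(ids[4:]), True)
        cutoff = 0.0

        minima = []
        for risk_idx in itertools.combinations(range(8), 4):
            a = sum(events[i] for i in risk_idx)
            c = 3 - a
            if a / 4 > cutoff:
                minima.append(fisher_enumeration_oracle(int(a), 4 - int(a), int(c), 4 - int(c)))
            else:
                minima.append(1.0)
        exact = np.quantile(minima, 0.05)

        est = p_cutoff_by_permutation(
            matrix, split, cutoff, AnalysisParams(n_perm_p=2000), rng=7
        )
        assert est == pytest.approx(exact, abs=0.02)

    def test_planted_association_beats_permutation_null(self):
        matrix, split = sixty_twentyone_matrix(n_risk_event=30, n_other_event=1)
        scan = probe_scan(
            matrix,
            split,
            cutoff=0.1,
            manifest=ProbeManifest.from_arrays(["prA"], ["1"], [100]),
        )
        observed = scan["p"].iloc[0]
        p_cut = p_cutoff_by_permutation(matrix, split, cutoff=0.1, rng=3)
        assert observed < p_cut

    def test_seeded_bit_reproducible(self):
        matrix, split = sixty_twentyone_matrix()
        a = p_cutoff_by_permutation(matrix, split, 0.1, rng=11)
        b = p_cutoff_by_permutation(matrix, split, 0.1, rng=11)
        assert a == b


class TestSignificantRegions:
    def _scan(self, ps, chroms=None, masked=None):
        n = len(ps)
        return pd.DataFrame(
            {
                "probe_id": [f"pr{i}" for i in range(n)],
                "chrom": chroms or ["1"] * n,
                "pos": list(range(100, 100 + n)),
                "a": 0, "b": 0, "c": 0, "d": 0,
                "masked": masked if masked is not None else [True] * n,
                "p": ps,
            }
        )

    def _manifest(self, n):
        return ProbeManifest.from_arrays(
            [f"pr{i}" for i in range(n)], ["1"] * n, list(range(100, 100 + n))
        )

    def test_runs_split_by_nonsignificant_probe(self):
        scan = self._scan([0.001, 0.002, 0.5, 0.003])
        regs = significant_regions(scan, 0.0085, self._manifest(4))
        assert len(regs) == 2
        assert regs.iloc[0]["n_probes"] == 2 and regs.iloc[1]["n_probes"] == 1

    def test_no_probe_passes(self):
        scan = self._scan([0.5, 0.9])
        assert significant_regions(scan, 0.0085, self._manifest(2)).empty

    def test_all_pass_single_region(self):
        scan = self._scan([0.001] * 4)
        regs = significant_regions(scan, 0.0085, self._manifest(4))
        assert len(regs) == 1 and regs.iloc[0]["n_probes"] == 4

    def test_runs_never_cross_chromosomes(self):
        scan = self._scan([0.001, 0.001], chroms=["1", "2"])
        regs = significant_regions(scan, 0.0085, self._manifest(2))
        assert len(regs) == 2

    def test_unmasked_probe_breaks_run(self):
        scan = self._scan([0.001, 0.001, 0.001], masked=[True, False, True])
        # unmasked probes carry NaN p in real scans; mimic that
        scan.loc[1, "p"] = np.nan
        regs = significant_regions(scan, 0.0085, self._manifest(3))
        assert len(regs) == 2
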