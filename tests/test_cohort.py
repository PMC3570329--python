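from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from mesadhere.claims_model import DrugClass, Product
from mesadhere.cohort import apply_exclusions, build_cohort, find_new_users
from conftest import DISPENSING_COLUMNS


def _disp(rows):
    """rows: (pid, iso-date, product or None for non-ASA)."""
    out = []
    for pid, date, product in rows:
        if product is None:
            out.append((pid, dt.date.fromisoformat(date), "ACETAMINOPHEN",
                        Product.OTHER.value, DrugClass.OTHER.value, 30, 30))
        else:
            out.append((pid, dt.date.fromisoformat(date), product.value,
                        product.value, DrugClass.FIVE_ASA.value, 120, 30))
    frame = pd.DataFrame(out, columns=DISPENSING_COLUMNS)
    return frame.sort_values(["patient_id", "dispense_date"]).reset_index(drop=True)


def _elig(rows):
    return pd.DataFrame(
        [(pid, dt.date.fromisoformat(a), dt.date.fromisoformat(b)) for pid, a, b in rows],
        columns=["patient_id", "start_date", "end_date"],
    )


def _patients(pids):
    return pd.DataFrame(
        [(pid, "FEMALE", 1950, "QC") for pid in pids],
        columns=["patient_id", "sex", "birth_year", "region"],
    )


EMPTY_MEDICAL = pd.DataFrame(columns=["patient_id", "service_date", "icd9_code"])


class TestFindNewUsers:
    def test_single_fill_with_clean_history_is_index(self):
        disp = _disp([("A", "2006-06-01", Product.PENTASA)])
        elig = _elig([("A", "2005-01-01", "2007-12-31")])
        candidates, excluded = find_new_users(disp, eligibility=elig)
        assert excluded == 0
        assert candidates.iloc[0].tolist() == ["A", dt.date(2006, 6, 1), "PENTASA"]

    def test_refill_is_not_a_second_index(self):
        disp = _disp([("A", "2006-06-01", Product.PENTASA), ("A", "2006-07-31", Product.PENTASA)])
        elig = _elig([("A", "2005-01-01", "2007-12-31")])
        candidates, _ = find_new_users(disp, eligibility=elig)
        assert len(candidates) == 1
        assert candidates.iloc[0]["index_date"] == dt.date(2006, 6, 1)

    def test_left_truncated_history_excluded(self):
        # eligibility begins 30 d before the first fill: washout unobservable
        disp = _disp([("A", "2006-06-01", Product.SALOFALK)])
        elig = _elig([("A", "2006-05-02", "2007-12-31")])
        candidates, excluded = find_new_users(disp, eligibility=elig)
        assert len(candidates) == 0 and excluded == 1

    def test_toy_stream_matches_brute_force_washout_scan(self):
        """Five constructed patients; expectation computed by exhaustive scan."""
        disp = _disp([
            ("P1", "2006-06-01", Product.ASACOL_OR_GENERIC),     # clean: qualifies
            ("P2", "2006-06-01", Product.PENTASA),               # washout unobservable
            ("P3", "2006-06-01", Product.SALOFALK),              # qualifies
            ("P3", "2006-06-20", Product.SALOFALK),
            ("P4", "2006-06-01", Product.MEZAVANT),              # eligibility hole in washout
            ("P5", "2006-06-01", Product.PENTASA),               # non-ASA claim doesn't matter
            ("P5", "2006-05-15", None),
        ])
        elig = _elig([
            ("P1", "2005-01-01", "2007-12-31"),
            ("P2", "2006-04-01", "2007-12-31"),
            ("P3", "2005-01-01", "2007-12-31"),
            ("P4", "2005-01-01", "2006-04-15"), ("P4", "2006-05-01", "2007-12-31"),
            ("P5", "2005-01-01", "2007-12-31"),
        ])
        candidates, excluded = find_new_users(disp, eligibility=elig)

        # independent oracle: scan every patient's earliest ASA fill by hand
        expected = set()
        for pid, group in disp[disp["drug_class"] == "FIVE_ASA"].groupby("patient_id"):
            first = group["dispense_date"].min()
            days = {first - dt.timedelta(days=k) for k in range(1, 91)}
            covered_days = set()
            for r in elig[elig["patient_id"] == pid].itertuples(index=False):
                d = r.start_date
                while d <= r.end_date:
                    covered_days.add(d)
                    d += dt.timedelta(days=1)
            if days <= covered_days:
                expected.add(pid)
        assert expected == {"P1", "P3", "P5"}
        assert set(candidates["patient_id"]) == expected
        assert excluded == 5 - len(expected)

    def test_all_drugs_washout_flag_excludes_prior_non_asa_claims(self):
        disp = _disp([("P5", "2006-06-01", Product.PENTASA), ("P5", "2006-05-15", None)])
        elig = _elig([("P5", "2005-01-01", "2007-12-31")])
        strict, excluded = find_new_users(disp, eligibility=elig, all_drugs_washout=True)
        assert len(strict) == 0 and excluded == 1


def _medical(rows):
    return pd.DataFrame(
        [(pid, dt.date.fromisoformat(d), code) for pid, d, code in rows],
        columns=["patient_id", "service_date", "icd9_code"],
    )


class TestExclusions:
    def _candidates(self, pids, index="2006-06-01"):
        return pd.DataFrame(
            [(pid, dt.date.fromisoformat(index), "PENTASA") for pid in pids],
            columns=["patient_id", "index_date", "index_product"],
        )

    def test_crohns_code_excluded_other_ibd_retained(self):
        candidates = self._candidates(["A", "B", "C"])
        medical = _medical([
            ("A", "2008-01-01", "555.9"),   # Crohn's: excluded, even post-index
            ("B", "2006-01-01", "556.9"),   # ulcerative colitis: retained
        ])
        elig = _elig([(p, "2005-01-01", "2008-12-31") for p in "ABC"])
        members, attrition = apply_exclusions(candidates, medical, elig, _patients("ABC"))
        assert {m.patient_id for m in members} == {"B", "C"}
        assert attrition.steps[0][1] == 1

    @pytest.mark.parametrize("code", [f"555.{k}" for k in range(10)] + ["555"])
    def test_all_crohns_subcodes_excluded(self, code):
        candidates = self._candidates(["A"])
        medical = _medical([("A", "2006-01-01", code)])
        elig = _elig([("A", "2005-01-01", "2008-12-31")])
        members, _ = apply_exclusions(candidates, medical, elig, _patients("A"))
        assert members == []

    def test_short_coverage_removed_and_counted(self):
        pids = [f"P{i}" for i in range(10)]
        candidates = self._candidates(pids)
        rows = []
        for i, pid in enumerate(pids):
            end = "2006-12-18" if i < 3 else "2008-12-31"  # day 200 post-index
            rows.append((pid, "2005-01-01", end))
        members, attrition = apply_exclusions(
            candidates, EMPTY_MEDICAL, _elig(rows), _patients(pids)
        )
        assert len(members) == 7
        assert dict(attrition.steps)["drug-plan coverage < 1 year post-index"] == 3

    def test_window_coverage_boundary_inclusive(self):
        # coverage ends exactly at index+364: retained; at index+363: excluded
        candidates = self._candidates(["A", "B"])
        elig = _elig([
            ("A", "2005-01-01", "2007-05-31"),  # index 2006-06-01 + 364 d
            ("B", "2005-01-01", "2007-05-30"),
        ])
        members, _ = apply_exclusions(candidates, EMPTY_MEDICAL, elig, _patients("AB"))
        assert {m.patient_id for m in members} == {"A"}

    def test_contiguous_split_periods_cover_window(self):
        candidates = self._candidates(["A"])
        elig = _elig([
            ("A", "2005-01-01", "2006-10-01"),
            ("A", "2006-10-02", "2008-12-31"),  # abuts: no hole
        ])
        members, _ = apply_exclusions(candidates, EMPTY_MEDICAL, elig, _patients("A"))
        assert len(members) == 1


class TestBuildCohort:
    def test_attrition_counts_sum_to_candidates_minus_members(self, small_sim):
        _, population, dispensing, medical, _ = small_sim
        members, attrition = build_cohort(
            dispensing, medical, population.eligibility, population.patients
        )
        assert attrition.n_candidates - attrition.n_removed == len(members)
        assert attrition.n_members == len(members)

    def test_cohort_invariant_to_input_row_order(self, small_sim):
        _, population, dispensing, medical, _ = small_sim
        members, _ = build_cohort(dispensing, medical, population.eligibility, population.patients)
        shuffled = dispensing.sample(frac=1, random_state=1).reset_index(drop=True)
        members2, _ = build_cohort(shuffled, medical, population.eligibility, population.patients)
        assert members == members2

    def test_members_satisfy_all_invariants(self, small_sim):
        """Washout, Crohn's-free, coverage: re-verified per member from raw data."""
        _, population, dispensing, medical, _ = small_sim
        members, _ = build_cohort(dispensing, medical, population.eligibility, population.patients)
        crohns = set(medical[medical["icd9_code"].str.startswith("555")]["patient_id"])
        asa = dispensing[dispensing["drug_class"] == "FIVE_ASA"]
        for m in members[:50]:
            assert m.patient_id not in crohns
            mine = asa[asa["patient_id"] == m.patient_id]["dispense_date"]
            assert not any(
                m.index_date - dt.timedelta(days=90) <= d < m.index_date for d in mine
            )
            spans = population.eligibility[population.eligibility["patient_id"] == m.patient_id]
            assert any(
                r.start_date <= m.index_date and r.end_date >= m.window_end
                for r in spans.itertuples(index=False)
            )
            assert m.age_at_index >= 0
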