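"""Two-criterion survey, functional classification and hypergeometric
enrichment, with brute-force and Monte-Carlo oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cbfsurvey.target_survey import (
    DEFAULT_CATEGORIES,
    classify,
    enrich,
    report,
    survey,
)


def fpkm_frame(winter, summer):
    genes = [f"g{i}" for i in range(len(winter))]
    return pd.DataFrame({"winter": winter, "summer": summer}, index=genes)


def brute_force_targets(table, hits, floor=0.1):
    """Independent naive intersection of the two criteria."""
    out = set()
    for g in table.index:
        a = max(table.at[g, "winter"], floor)
        b = max(table.at[g, "summer"], floor)
        if abs(math.log2(a / b)) >= 1 and hits.get(g, 0) >= 1:
            out.add(g)
    return out


def test_survey_applies_both_criteria():
    table = fpkm_frame([30, 30, 15, 2], [10, 10, 10, 10])
    hits = {"g0": 1, "g1": 0, "g2": 2, "g3": 3}
    records, summary = survey(table, hits, "winter", "summer")
    got = {r.gene_id: r.direction for r in records}
    # g0: fc 3 + hit -> up; g1: no hit; g2: fc 1.5; g3: fc 0.2 + hit -> down
    assert got == {"g0": "up", "g3": "down"}
    assert summary["total"] == 2 and summary["up"] == 1 and summary["down"] == 1


def test_survey_unknown_condition():
    with pytest.raises(KeyError):
        survey(fpkm_frame([1], [1]), {}, "winter", "autumn")


@pytest.mark.parametrize("trial", range(20))
def test_survey_equals_bruteforce_intersection(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(5, 200))
    table = fpkm_frame(
        rng.uniform(0, 40, size=n).round(3), rng.uniform(0, 40, size=n).round(3)
    )
    hits = {f"g{i}": int(rng.integers(0, 3)) for i in range(n)}
    records, summary = survey(table, hits, "winter", "summer")
    assert {r.gene_id for r in records} == brute_force_targets(table, hits)
    assert summary["up"] + summary["down"] == summary["total"]


def test_survey_planted_truth(genome_fixture, counts_fixture):
    from cbfsurvey import synthetic_data as sd
    from cbfsurvey.expression import expression_matrix
    from cbfsurvey.promoter_scan import count_hits, extract_promoters

    m = expression_matrix(counts_fixture.table)
    hits = count_hits(extract_promoters(genome_fixture.genes, genome_fixture.contigs))
    records, summary = survey(m, hits, sd.WINTER, sd.SUMMER)
    truth = counts_fixture.truth
    spec = sd.FixtureSpec()
    assert summary["total"] == spec.n_up + spec.n_down
    assert summary["up"] == spec.n_up and summary["down"] == spec.n_down
    for r in records:
        assert truth[r.gene_id]["direction"] == r.direction


def test_classify_keyword_matching():
    from cbfsurvey.target_survey import SurveyRecord

    recs = [
        SurveyRecord("g1", 4, 2, "up", 1),
        SurveyRecord("g2", 4, 2, "up", 1),
        SurveyRecord("g3", 0.2, -2.3, "down", 2),
    ]
    annotations = {
        "g1": "galactinol synthase 2",
        "g2": "receptor-like protein KINASE with calmodulin-binding domain",
        "g3": "hypothetical protein",
    }
    classify(recs, annotations)
    assert recs[0].categories == ("carbohydrate metabolism",)
    assert set(recs[1].categories) == {"calcium signaling", "kinase"}
    assert recs[2].categories == ("other",)


def test_classify_multi_category_order_deterministic():
    from cbfsurvey.target_survey import SurveyRecord

    recs = [SurveyRecord("g", 4, 2, "up", 1)]
    classify(recs, {"g": "calcium-transporting ATPase"})
    # keyword-map order: calcium signaling before transporter
    assert recs[0].categories == ("calcium signaling", "transporter")


def test_classify_rejects_empty_map():
    with pytest.raises(ValueError):
        classify([], {}, keyword_map={})


def test_enrich_exact_small_case():
    # M=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
    background = [f"b{i}" for i in range(10)]
    surv = background[:4]
    term_map = {"T": background[:4] + [background[5]]}  # K=5 incl. all survey
    # annotate everything via a catch-all term so M=10, n=4
    term_map["ALL"] = background
    res = {e.term: e for e in enrich(surv, background, term_map)}
    assert res["T"].k == 4 and res["T"].K == 5 and res["T"].n == 4 and res["T"].M == 10
    assert res["T"].p == pytest.approx(5 / 210)


def test_enrich_exhaustive_enumeration_oracle():
    import itertools

    background = list("abcdefghij")
    surv = list("abcd")
    term_genes = set("abcdf")
    term_map = {"T": sorted(term_genes), "ALL": background}
    res = {e.term: e for e in enrich(surv, background, term_map)}
    # enumerate all C(10,4) draws; count those with >= k term genes
    k = len(term_genes & set(surv))
    count = sum(
        1
        for combo in itertools.combinations(background, 4)
        if len(set(combo) & term_genes) >= k
    )
    assert res["T"].p == pytest.approx(count / math.comb(10, 4))


def test_enrich_full_term_has_p_one():
    background = [f"b{i}" for i in range(8)]
    res = enrich(background[:3], background, {"ALL": background})
    assert res[0].p == pytest.approx(1.0)


def test_enrich_monte_carlo_oracle(rng):
    M, K, n = 40, 12, 15
    background = [f"g{i}" for i in range(M)]
    term = set(background[:K])
    surv = background[5 : 5 + n]
    k = len(term & set(surv))
    res = {e.term: e for e in enrich(surv, background, {"T": sorted(term), "ALL": background})}
    draws = 100_000
    sims = rng.hypergeometric(K, M - K, n, size=draws)
    mc = float(np.mean(sims >= k))
    se = math.sqrt(mc * (1 - mc) / draws)
    assert abs(res["T"].p - mc) < 3 * max(se, 1e-4)


def test_enrich_bh_monotone_and_label_invariant(rng):
    M = 30
    background = [f"g{i}" for i in range(M)]
    term_map = {
        f"T{j}": list(rng.choice(background, size=int(rng.integers(3, 12)), replace=False))
        for j in range(6)
    }
    surv = list(rng.choice(background, size=10, replace=False))
    res = enrich(surv, background, term_map)
    # sorted by p; BH adjusted values >= raw and monotone in rank order
    ps = [e.p for e in res]
    assert ps == sorted(ps)
    for e in res:
        assert e.p_adj >= e.p - 1e-12
    # relabeling genes leaves p-values unchanged
    mapping = {g: f"x{g}" for g in background}
    res2 = enrich(
        [mapping[g] for g in surv],
        [mapping[g] for g in background],
        {t: [mapping[g] for g in gs] for t, gs in term_map.items()},
    )
    assert [e.p for e in res2] == pytest.approx([e.p for e in res])


def test_enrich_rejects_survey_outside_background():
    with pytest.raises(ValueError):
        enrich(["z"], ["a", "b"], {"T": ["a"]})


def test_report_totals_and_category_conservation():
    from cbfsurvey.target_survey import SurveyRecord

    recs = [
        SurveyRecord("g1", 4, 2, "up", 1, categories=("kinase",)),
        SurveyRecord("g2", 0.1, -3.3, "down", 1, categories=("kinase",)),
        SurveyRecord("g3", 8, 3, "up", 2, categories=("other",)),
    ]
    rep = report(recs)
    assert rep["totals"] == {"total": 3, "up": 2, "down": 1}
    for cat, c in rep["categories"].items():
        assert c["up"] + c["down"] == c["total"]
    assert rep["categories"]["kinase"]["total"] == 2


def test_report_empty_survey():
    rep = report([])
    assert rep["totals"] == {"total": 0, "up": 0, "down": 0}
    assert rep["enrichment"] == []
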