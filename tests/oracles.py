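"""Independent brute-force oracles: naive per-person scans used to verify
the vectorized engines on small bundles."""

from collections import defaultdict

import pandas as pd

from amiclaims.cohort import StudyConfig, continuously_enrolled, era_valid

_POSITION_RANK = {"principal": 0, "secondary": 1, "unspecified": 2}


def naive_cohort(bundle, codelist, period, scope_settings, config=None):
    """Per-person scan of every claim under the inclusion rules.

    Returns (events dict person_id -> (date, setting_rank, position_rank,
    code, version, setting), denominator count).
    """
    config = config or StudyConfig()
    spans = defaultdict(list)
    for r in bundle.enrollment.itertuples():
        spans[r.person_id].append((pd.Timestamp(r.start_date).date(), pd.Timestamp(r.end_date).date()))
    years = period.calendar_years()
    eligible_years: dict[str, set[int]] = {}
    for r in bundle.persons.itertuples():
        ys = {
            y for y in years
            if y - r.birth_year >= config.min_age_years
            and continuously_enrolled(spans[r.person_id], y, config.enrollment_gap_days)
        }
        if ys:
            eligible_years[r.person_id] = ys
    best: dict[str, tuple] = {}
    for r in bundle.diagnoses.itertuples():
        d = pd.Timestamp(r.service_date).date()
        if not (period.start <= d <= period.end):
            continue
        if not (config.study_start <= d <= config.study_end):
            continue
        if not era_valid(r.version, d, config):
            continue
        if r.setting not in scope_settings:
            continue
        if not codelist.matches(r.code, r.version):
            continue
        if r.person_id not in eligible_years or d.year not in eligible_years[r.person_id]:
            continue
        key = (d, 0 if r.setting == "inpatient" else 1, _POSITION_RANK[r.position],
               r.code, r.version, r.setting)
        if r.person_id not in best or key < best[r.person_id]:
            best[r.person_id] = key
    return best, len(eligible_years)


def naive_windowed_counts(cohort, claims, window, item_col, date_col):
    """Per-person date filter: item -> number of distinct persons."""
    index_dates = dict(zip(cohort.events["person_id"], pd.to_datetime(cohort.events["index_date"])))
    seen = defaultdict(set)
    for r in claims.itertuples():
        pid = r.person_id
        if pid not in index_dates:
            continue
        off = (pd.Timestamp(getattr(r, date_col)) - index_dates[pid]).days
        if window.rel_start <= off <= window.rel_end:
            seen[getattr(r, item_col)].add(pid)
    return {k: len(v) for k, v in seen.items()}


def gem_closure(seed, forward, backward):
    """Transitive reachability over the two GEM relations (ignoring no-map
    entries): the fixed point that iterated forward-backward mapping must
    converge to."""
    fmap = defaultdict(set)
    bmap = defaultdict(set)
    for e in forward.entries:
        if not e.no_map:
            fmap[e.source].add(e.target)
    for e in backward.entries:
        if not e.no_map:
            bmap[e.source].add(e.target)
    src = set(seed)
    tgt = set()
    while True:
        new_tgt = {t for s in src for t in fmap[s]} - tgt
        tgt |= new_tgt
        new_src = {t for s in tgt for t in bmap[s]} - src
        src |= new_src
        if not new_tgt and not new_src:
            return src, tgt
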