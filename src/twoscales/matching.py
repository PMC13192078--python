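"""Exact 1-to-1 matching of Post to Pre subjects on the calendar admission day.

Matching balances the study-entry (admission-date) distribution between the
two groups, which removes the calendar-time structural bias without modelling
a second time scale.  Each Post subject, visited in seeded random order, draws
a Pre partner uniformly without replacement from the Pre subjects admitted on
exactly the same calendar day; Post subjects with no remaining candidate stay
unmatched.  Transitional subjects are ignored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PAIR_COLUMNS = ["pair_id", "pre_subject_id", "post_subject_id", "admission_day"]


def match_one_to_one(
    cohort: pd.DataFrame,
    seed: int,
    within_hospital: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match Post to Pre subjects sharing the exact admission day.

    Returns ``(pairs, unmatched)``: pairs with columns ``pair_id,
    pre_subject_id, post_subject_id, admission_day`` and the unmatched Post
    subjects with the number of same-day Pre candidates that existed before
    matching.  Deterministic given ``seed``.  With ``within_hospital`` the
    partner must additionally come from the same hospital (off by default).
    """
    rng = np.random.default_rng(seed)
    pre = cohort[cohort["group"] == "Pre"]
    post = cohort[cohort["group"] == "Post"]

    def key(row_day, row_hosp):
        return (row_day, row_hosp) if within_hospital else row_day

    pools: dict = {}
    for sid, day, hosp in zip(
        pre["subject_id"], pre["admission_day"], pre["hospital_id"]
    ):
        pools.setdefault(key(day, hosp), []).append(sid)
    initial_sizes = {k: len(v) for k, v in pools.items()}

    post_idx = rng.permutation(len(post))
    post_ids = post["subject_id"].to_numpy()
    post_days = post["admission_day"].to_numpy()
    post_hosps = post["hospital_id"].to_numpy()

    rows, unmatched = [], []
    n_pairs = 0
    for i in post_idx:
        k = key(post_days[i], post_hosps[i])
        pool = pools.get(k)
        if pool:
            j = int(rng.integers(len(pool)))
            pool[j], pool[-1] = pool[-1], pool[j]  # swap-pop: uniform w/o replacement
            partner = pool.pop()
            rows.append((f"pair_{n_pairs:06d}", partner, post_ids[i], post_days[i]))
            n_pairs += 1
        else:
            unmatched.append((post_ids[i], post_days[i], initial_sizes.get(k, 0)))
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS).sort_values(
        "admission_day", kind="stable", ignore_index=True
    )
    unmatched_df = pd.DataFrame(
        unmatched, columns=["post_subject_id", "admission_day", "n_pre_same_day"]
    ).sort_values("admission_day", kind="stable", ignore_index=True)
    return pairs, unmatched_df


def matched_cohort(pairs: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Restrict a cohort to matched subjects, tagging each with its pair id.

    The result has ``2 * len(pairs)`` rows and a ``pair_id`` column, the
    clustering unit for marginal Cox models on matched data (matching induces
    within-pair correlation).  By construction the admission-day distribution
    is exactly balanced between the Pre and Post halves.
    """
    ids = pd.concat(
        [
            pairs[["pre_subject_id", "pair_id"]].rename(
                columns={"pre_subject_id": "subject_id"}
            ),
            pairs[["post_subject_id", "pair_id"]].rename(
                columns={"post_subject_id": "subject_id"}
            ),
        ],
        ignore_index=True,
    )
    unknown = set(ids["subject_id"]) - set(cohort["subject_id"])
    if unknown:
        raise ValueError(f"pairs reference unknown subjects: {sorted(unknown)}")
    out = cohort.merge(ids, on="subject_id", how="inner")
    if len(out) != 2 * len(pairs):
        raise ValueError("pair members missing from or duplicated in cohort")
    return out.reset_index(drop=True)
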