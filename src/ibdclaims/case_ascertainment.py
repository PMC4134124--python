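"""Scored case ascertainment from claim and discharge streams.

The case definition (a variant of the validated Alberta administrative
definition) has four parts:

1. *Code mapping*: ICD-9 stems 555/556 and ICD-10 stems K50/K51 map to CD and
   UC respectively; everything else is ignored.
2. *IBD gate*: at least one hospital discharge, or at least four physician
   claims within a rolling two-year window, all with an IBD-mapped code.
3. *Washout*: anyone with an IBD-mapped encounter during the pre-study
   washout years (1991-1995 in the default profile) is treated as prevalent
   and excluded.
4. *Subtype score*: each claim scores +1 (UC code) or -1 (CD code), each
   discharge +2/-2; the cumulative score classifies UC (> +2), CD (< -2) or
   undifferentiated IBD (between -2 and +2 inclusive).

The diagnosis date is the first IBD-coded contact on/after the study start,
and the incidence year is the year of that date.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GateRule, ScoreWeights
from .errors import DataError

_ICD9_STEMS = {"555": "CD", "556": "UC"}
_ICD10_STEMS = {"K50": "CD", "K51": "UC"}


def map_code(code: str, icd_version: int) -> str | None:
    """Map one diagnosis code to ``"CD"``, ``"UC"`` or ``None``.

    Matching is prefix-based on the stem before any decimal point and
    case-insensitive, so ``556.9``, ``5569`` and ``k51`` all map.
    Unknown codes are silently non-target, never errors.
    """
    stem = str(code).strip().upper().split(".", 1)[0]
    table = _ICD9_STEMS if int(icd_version) == 9 else _ICD10_STEMS
    for prefix, disease in table.items():
        if stem.startswith(prefix):
            return disease
    return None


def map_codes(encounters: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`map_code` over an encounter table."""
    stem = encounters["code"].astype(str).str.strip().str.upper().str.split(".").str[0]
    v9 = encounters["icd_version"].astype(int) == 9
    out = pd.Series(np.full(len(encounters), None, dtype=object), index=encounters.index)
    out[v9 & stem.str.startswith("555")] = "CD"
    out[v9 & stem.str.startswith("556")] = "UC"
    out[~v9 & stem.str.startswith("K50")] = "CD"
    out[~v9 & stem.str.startswith("K51")] = "UC"
    return out


def _check_sorted(dates: np.ndarray) -> None:
    if len(dates) > 1 and (np.diff(dates) < np.timedelta64(0, "D")).any():
        raise DataError("meets_ibd_gate: encounters must be sorted by date")


def _window_completion(dates: np.ndarray, k: int, window_days: int):
    """Earliest date at which some half-open window [t, t+window) holds k events.

    Windows are anchored at event dates; the completion date is the k-th
    event's date in the earliest qualifying window.  Because the k-th-event
    index grows with the anchor, the first qualifying anchor yields the
    earliest completion.
    """
    window = np.timedelta64(int(window_days), "D")
    for i in range(len(dates) - k + 1):
        if dates[i + k - 1] - dates[i] < window:
            return dates[i + k - 1]
    return None


def meets_ibd_gate(
    encounters: pd.DataFrame, rule: GateRule = GateRule()
) -> tuple[bool, np.datetime64 | None]:
    """Test the IBD entry criterion on one person's IBD-mapped encounters.

    ``encounters`` must be sorted by date and contain only IBD-mapped rows of
    a single person.  Returns ``(qualified, qualifying_date)`` where the
    qualifying date is the earliest date at which either arm of the criterion
    is first satisfied.
    """
    dates = pd.to_datetime(encounters["date"]).to_numpy().astype("M8[D]")
    _check_sorted(dates)
    source = encounters["source"].to_numpy()

    candidates = []
    d = _window_completion(dates[source == "discharge"], rule.min_hospitalizations, rule.window_days)
    if d is not None:
        candidates.append(d)
    c = _window_completion(dates[source == "claim"], rule.min_claims, rule.window_days)
    if c is not None:
        candidates.append(c)
    if not candidates:
        return False, None
    return True, min(candidates)


def cumulative_score(encounters: pd.DataFrame, weights: ScoreWeights = ScoreWeights()) -> int:
    """Sum of per-encounter scores over IBD-mapped encounters.

    Requires a ``disease`` column (``"CD"``/``"UC"``); claims weigh +/-1 and
    discharges +/-2 under the default weights.  An empty table scores 0.
    """
    if len(encounters) == 0:
        return 0
    claim = encounters["source"].to_numpy() == "claim"
    uc = encounters["disease"].to_numpy() == "UC"
    w = np.where(
        claim,
        np.where(uc, weights.claim_uc, weights.claim_cd),
        np.where(uc, weights.discharge_uc, weights.discharge_cd),
    )
    return int(w.sum())


def classify(score: int, weights: ScoreWeights = ScoreWeights()) -> str:
    """UC above the UC threshold, CD below the CD threshold, IBDU between."""
    if score > weights.uc_threshold:
        return "UC"
    if score < weights.cd_threshold:
        return "CD"
    return "IBDU"


def apply_washout(encounters: pd.DataFrame, washout_span: tuple[int, int]) -> bool:
    """True (exclude as prevalent) iff any IBD-mapped encounter falls in the washout years."""
    if len(encounters) == 0:
        return False
    years = pd.to_datetime(encounters["date"]).dt.year
    return bool(((years >= washout_span[0]) & (years <= washout_span[1])).any())


def ascertain_cases(
    registry: pd.DataFrame,
    encounters: pd.DataFrame,
    gate: GateRule = GateRule(),
    weights: ScoreWeights = ScoreWeights(),
    washout_span: tuple[int, int] = (1991, 1995),
    study_span: tuple[int, int] = (1996, 2009),
    classification_window_days: int | None = 730,
) -> pd.DataFrame:
    """Run the full case definition over a cohort.

    Per person: keep IBD-mapped encounters, exclude on washout, test the
    gate, date the diagnosis at the first IBD-coded contact on/after the
    study start, score the encounters within ``classification_window_days``
    of the person's first IBD contact (``None`` = all follow-up) and
    classify.  Persons whose diagnosis year falls outside ``study_span`` are
    dropped.

    Returns a cases table with columns person_id, diagnosis_date,
    diagnosis_year, score, category, n_claims, n_discharges.
    """
    if registry["person_id"].duplicated().any():
        raise DataError("ascertain_cases: duplicate person_id in registry")
    known = set(registry["person_id"])
    extra = set(encounters["person_id"]) - known
    if extra:
        raise DataError(f"ascertain_cases: encounters refer to unknown persons (e.g. {sorted(extra)[:3]})")

    enc = encounters.copy()
    enc["disease"] = map_codes(enc)
    ibd = enc[enc["disease"].notna()]
    ibd = ibd.sort_values(["person_id", "date"], kind="mergesort")

    study_start = np.datetime64(f"{study_span[0]}-01-01", "D")
    rows = []
    for pid, g in ibd.groupby("person_id", sort=True):
        if apply_washout(g, washout_span):
            continue
        qualified, _ = meets_ibd_gate(g, gate)
        if not qualified:
            continue
        dates = pd.to_datetime(g["date"]).to_numpy().astype("M8[D]")
        on_study = dates[dates >= study_start]
        if len(on_study) == 0:
            continue
        diagnosis_date = on_study[0]
        diagnosis_year = int(diagnosis_date.astype("M8[Y]").astype("int64")) + 1970
        if not (study_span[0] <= diagnosis_year <= study_span[1]):
            continue
        first_contact = dates[0]
        if classification_window_days is None:
            win = g
        else:
            horizon = first_contact + np.timedelta64(int(classification_window_days), "D")
            win = g[(dates >= first_contact) & (dates <= horizon)]
        score = cumulative_score(win, weights)
        rows.append(
            {
                "person_id": pid,
                "diagnosis_date": diagnosis_date,
                "diagnosis_year": diagnosis_year,
                "score": score,
                "category": classify(score, weights),
                "n_claims": int((win["source"] == "claim").sum()),
                "n_discharges": int((win["source"] == "discharge").sum()),
            }
        )
    if not rows:
        return pd.DataFrame(
            {
                "person_id": pd.Series(dtype="int64"),
                "diagnosis_date": pd.Series(dtype="datetime64[s]"),
                "diagnosis_year": pd.Series(dtype="int64"),
                "score": pd.Series(dtype="int64"),
                "category": pd.Series(dtype=object),
                "n_claims": pd.Series(dtype="int64"),
                "n_discharges": pd.Series(dtype="int64"),
            }
        )
    cases = pd.DataFrame(rows)
    cases["diagnosis_date"] = pd.to_datetime(cases["diagnosis_date"])
    return cases


def write_cases(path, cases: pd.DataFrame) -> None:
    out = cases.copy()
    out["diagnosis_date"] = pd.to_datetime(out["diagnosis_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
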