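"""Simon-task scoring and the MCI case definition.

Trials live in a pandas ``TrialTable`` (one row per trial).  The cue colour
fixes the required response: blue -> right hand, red -> left hand,
yellow -> withhold the response.  A trial is correct when the given
response equals the required one; for the no-response condition that means
no button press at all.  Reaction-time summaries (median and IQR, type-7
linear-interpolation quantiles) are computed over correct, responded
trials; the no-response condition has no reaction times by construction.

Case definition: a participant is globally impaired when MMSE < 24;
otherwise they are MCI when any cognitive-domain score lies 1.5 standard
deviations or more below the age- and education-stratified normative mean
(timed tests are sign-flipped so that higher always means better before
z-scoring), and healthy-control (HC) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("congruent", "incongruent", "no_response")
COLOR_TO_RESPONSE = {"blue": "right", "red": "left", "yellow": "none"}

#: cognitive domains -> (subject-table column, higher-is-better flag)
DOMAINS = {
    "memory": ("word_list_memory", True),
    "attention": ("tmt_a", False),
    "executive": ("tmt_b", False),
    "processing_speed": ("sdst", True),
}

MMSE_CUTOFF = 24
MCI_Z_THRESHOLD = -1.5


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of a trial table."""
    required = {"trial_index", "condition", "cue_side", "cue_color",
                "correct_response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    bad = set(trials["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    expect = trials["cue_color"].map(COLOR_TO_RESPONSE)
    if not (expect == trials["correct_response"]).all():
        raise ValueError("correct_response inconsistent with cue colour mapping")
    return trials


@dataclass
class ConditionScore:
    n_trials: int
    percent_correct: float | None  # None when the condition is empty
    rt_median_s: float | None = None
    rt_iqr_s: tuple[float, float] | None = None


@dataclass
class BehaviorSummary:
    subject_id: str
    conditions: dict[str, ConditionScore] = field(default_factory=dict)

    def as_row(self) -> dict:
        row: dict = {"subject_id": self.subject_id}
        for cond, sc in self.conditions.items():
            row[f"acc_{cond}"] = sc.percent_correct
            if sc.rt_median_s is not None:
                row[f"rt_{cond}"] = sc.rt_median_s
        return row


def score_trials(trials: pd.DataFrame, subject_id: str = "subject") -> BehaviorSummary:
    """Per-condition proportion correct (%) and RT median/IQR (s)."""
    validate_trial_table(trials)
    if "given_response" not in trials.columns:
        raise ValueError("trial table has no responses to score")
    out = BehaviorSummary(subject_id=subject_id)
    for cond in CONDITIONS:
        sub = trials[trials["condition"] == cond]
        if len(sub) == 0:
            out.conditions[cond] = ConditionScore(0, None)
            continue
        correct = sub["given_response"] == sub["correct_response"]
        score = ConditionScore(
            n_trials=len(sub),
            percent_correct=100.0 * float(correct.mean()),
        )
        if cond != "no_response":
            rts = sub.loc[correct & (sub["given_response"] != "none"), "rt_s"]
            rts = rts.dropna().to_numpy(float)
            if len(rts):
                score.rt_median_s = float(np.median(rts))
                q1, q3 = np.quantile(rts, [0.25, 0.75])  # type-7 default
                score.rt_iqr_s = (float(q1), float(q3))
        out.conditions[cond] = score
    return out


@dataclass(frozen=True)
class CognitiveNorms:
    """Normative means/SDs per domain, stratified by age and education bands.

    ``table`` columns: domain, age_min, age_max, edu_min, edu_max, mean, sd
    (bands are closed intervals).  The exact stratification of the
    normative database is a configuration matter; synthetic norms ship with
    the generator.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"domain", "age_min", "age_max", "edu_min", "edu_max",
                    "mean", "sd"}
        if required - set(self.table.columns):
            raise ValueError(f"norms table needs columns {sorted(required)}")
        if (self.table["sd"] <= 0).any():
            raise ValueError("normative SDs must be positive")

    def lookup(self, domain: str, age: float, education: float) -> tuple[float, float]:
        t = self.table
        hit = t[(t["domain"] == domain)
                & (t["age_min"] <= age) & (age <= t["age_max"])
                & (t["edu_min"] <= education) & (education <= t["edu_max"])]
        if len(hit) == 0:
            raise KeyError(
                f"no normative stratum for domain={domain!r}, age={age}, "
                f"education={education}"
            )
        row = hit.iloc[0]
        return float(row["mean"]), float(row["sd"])

    @classmethod
    def single_stratum(cls, means_sds: dict[str, tuple[float, float]]) -> "CognitiveNorms":
        """Norms with one all-ages/all-education stratum per domain."""
        rows = [
            {"domain": d, "age_min": 0, "age_max": 200, "edu_min": 0,
             "edu_max": 100, "mean": m, "sd": s}
            for d, (m, s) in means_sds.items()
        ]
        return cls(table=pd.DataFrame(rows))


def domain_z_scores(record: pd.Series | dict, norms: CognitiveNorms) -> dict[str, float]:
    """Z-score each cognitive domain against its normative stratum
    (higher z = better for every domain)."""
    rec = pd.Series(record) if isinstance(record, dict) else record
    zs = {}
    for domain, (col, higher_better) in DOMAINS.items():
        mean, sd = norms.lookup(domain, rec["age"], rec["education"])
        z = (rec[col] - mean) / sd
        zs[domain] = float(z if higher_better else -z)
    return zs


def classify_mci(record: pd.Series | dict, norms: CognitiveNorms) -> str:
    """Label a subject HC / MCI / global_impairment from cognition alone."""
    rec = pd.Series(record) if isinstance(record, dict) else record
    for col in ["mmse", "age", "education"] + [c for c, _ in DOMAINS.values()]:
        if col not in rec or pd.isna(rec[col]):
            raise ValueError(f"missing field required for classification: {col}")
    if rec["mmse"] < MMSE_CUTOFF:
        return "global_impairment"
    zs = domain_z_scores(rec, norms)
    if any(z <= MCI_Z_THRESHOLD for z in zs.values()):
        return "MCI"
    return "HC"
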