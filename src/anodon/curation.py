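"""Analysis-time curation of the donation store.

Because donations carry no identifier of any kind, repeated quarterly
donations from one donor can only be recognized from content: each later
snapshot contains a significantly large subset of the donor's previous one.
Curation therefore (1) links donations into presumed donors by directional
row-containment, keeping the latest snapshot per donor, (2) removes
physiologically impossible rows with per-category plausibility intervals,
and (3) excludes statistical outliers with a robust median/MAD rule.

Content-based linkage is heuristic by nature: two donors with coincidentally
identical tiny snapshots will merge, and a donor who wipes their dataset
will split.  Duplicates can be reduced, not eliminated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .payload import DonationPayload, HealthRecordRow, render_value

#: linkage threshold: the fraction of an earlier snapshot that must reappear
DEFAULT_OVERLAP_THRESHOLD = 0.8

#: MAD multiplier for statistical outlier exclusion
DEFAULT_MAD_K = 5.0

#: minimum pooled sample size before the outlier rule activates
MIN_OUTLIER_SAMPLES = 10

_SEP = "\x1f"


def row_keys(payload: DonationPayload) -> frozenset[str]:
    """Canonical content-derived identity of every row in a payload.

    Row identity includes the value itself, not just category and date:
    full snapshots re-donate identical historical rows verbatim, and
    value-inclusion keeps coincidental cross-donor collisions rare.
    """
    keys = set()
    for r in payload.rows:
        keys.add(
            _SEP.join(
                ("h", r.category, r.observed_date.isoformat(), render_value(r.value), r.analyte)
            )
        )
    for q in payload.questionnaire:
        keys.add(_SEP.join(("q", q.key, q.answer)))
    return frozenset(keys)


def overlap(earlier: DonationPayload | frozenset[str], later: DonationPayload | frozenset[str]) -> float:
    """Directional containment: the fraction of the earlier snapshot's rows
    present in the later one.  Not symmetric.  An empty earlier snapshot
    carries no linkage evidence and scores 0."""
    ek = earlier if isinstance(earlier, frozenset) else row_keys(earlier)
    lk = later if isinstance(later, frozenset) else row_keys(later)
    if not ek:
        return 0.0
    return len(ek & lk) / len(ek)


@dataclass
class DonorCluster:
    """Donations attributed to one presumed donor, in receipt order."""

    donation_ids: list[str]
    receipt_indices: list[int] = field(default_factory=list)

    @property
    def representative_id(self) -> str:
        return self.donation_ids[-1]  # latest by receipt order

    @property
    def size(self) -> int:
        return len(self.donation_ids)


def cluster_donations(
    donations: list[tuple[str, DonationPayload]],
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> list[DonorCluster]:
    """Greedy chronological linkage of donations into presumed donors.

    Donations are scanned in receipt order.  Each one is compared against
    the current tail (latest member) of every existing cluster; it joins the
    cluster whose tail it best continues, iff that best overlap reaches the
    threshold, with ties broken toward the most recent tail.  Otherwise it
    founds a new cluster.  The result is a partition; the number of clusters
    is the presumed unique-donor count.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    clusters: list[DonorCluster] = []
    tails: list[frozenset[str]] = []  # row keys of each cluster's tail
    for idx, (donation_id, payload) in enumerate(donations):
        keys = row_keys(payload)
        best_i, best_score, best_recency = -1, -1.0, -1
        for ci, tail_keys in enumerate(tails):
            score = overlap(tail_keys, keys)
            recency = clusters[ci].receipt_indices[-1]
            if score > best_score or (score == best_score and recency > best_recency):
                best_i, best_score, best_recency = ci, score, recency
        if best_i >= 0 and best_score >= threshold:
            clusters[best_i].donation_ids.append(donation_id)
            clusters[best_i].receipt_indices.append(idx)
            tails[best_i] = keys
        else:
            clusters.append(DonorCluster([donation_id], [idx]))
            tails.append(keys)
    return clusters


def latest_per_donor(
    clusters: list[DonorCluster], donations: list[tuple[str, DonationPayload]]
) -> list[tuple[str, DonationPayload]]:
    """The representative (latest) donation of each cluster — ideally the
    only snapshot used for further analysis."""
    by_id = dict(donations)
    return [(c.representative_id, by_id[c.representative_id]) for c in clusters]


@dataclass(frozen=True)
class PlausibilityRule:
    """Closed-form admissible interval for one category; each bound may be
    inclusive or exclusive, or infinite for analyte-specific categories."""

    low: float
    high: float
    low_inclusive: bool = True
    high_inclusive: bool = True

    def admits(self, value: float) -> bool:
        if self.low_inclusive:
            if value < self.low:
                return False
        elif value <= self.low:
            return False
        if self.high_inclusive:
            if value > self.high:
                return False
        elif value >= self.high:
            return False
        return True


#: physiological admissibility per category; a resting heart rate above
#: 250 bpm is impossible, hence the half-open (20, 250] interval
DEFAULT_PLAUSIBILITY_RULES: dict[str, PlausibilityRule] = {
    "resting_heart_rate": PlausibilityRule(20, 250, low_inclusive=False),
    "blood_pressure_systolic": PlausibilityRule(60, 260),
    "blood_pressure_diastolic": PlausibilityRule(30, 160),
    "sleep_duration": PlausibilityRule(0, 24),
    "steps": PlausibilityRule(0, 200000),
    "lab_result": PlausibilityRule(-math.inf, math.inf),  # analyte-specific
}


def rules_from_yaml(text: str) -> dict[str, PlausibilityRule]:
    """Load per-category rules from YAML: ``category: {low, high,
    low_inclusive, high_inclusive}``; ``.inf``/``-.inf`` are accepted."""
    doc = yaml.safe_load(text)
    rules = {}
    for category, spec in doc.items():
        rules[category] = PlausibilityRule(
            low=float(spec["low"]),
            high=float(spec["high"]),
            low_inclusive=bool(spec.get("low_inclusive", True)),
            high_inclusive=bool(spec.get("high_inclusive", True)),
        )
    return rules


@dataclass(frozen=True)
class PlausibilityRejection:
    row: HealthRecordRow
    rule: PlausibilityRule


def plausibility_filter(
    payload: DonationPayload,
    rules: dict[str, PlausibilityRule] | None = None,
) -> tuple[DonationPayload, list[PlausibilityRejection]]:
    """Drop rows whose value lies outside the category's admissible interval.

    Questionnaire entries are closed-vocabulary and pass untouched.  The
    operation is idempotent: filtering a filtered payload removes nothing.
    """
    rules = DEFAULT_PLAUSIBILITY_RULES if rules is None else rules
    kept, rejected = [], []
    for r in payload.rows:
        rule = rules[r.category]
        if rule.admits(r.value):
            kept.append(r)
        else:
            rejected.append(PlausibilityRejection(r, rule))
    return (
        DonationPayload(rows=tuple(kept), questionnaire=payload.questionnaire),
        rejected,
    )


@dataclass(frozen=True)
class OutlierExclusion:
    group: tuple[str, str]  # (category, analyte)
    row: HealthRecordRow
    median: float
    mad: float


def outlier_filter(
    payloads: list[DonationPayload], k: float = DEFAULT_MAD_K
) -> tuple[list[DonationPayload], list[OutlierExclusion]]:
    """Exclude rows whose value deviates from the pooled per-category median
    by more than ``k`` median absolute deviations.

    Values are pooled across all given payloads per (category, analyte)
    group.  Groups with fewer than 10 values pass through, as do groups with
    zero MAD (a constant has no scale to judge deviation against).
    Deterministic given inputs, and idempotent at fixed reference statistics.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for p in payloads:
        for r in p.rows:
            groups.setdefault((r.category, r.analyte), []).append(r.value)
    stats: dict[tuple[str, str], tuple[float, float]] = {}
    for g, values in groups.items():
        if len(values) < MIN_OUTLIER_SAMPLES:
            continue
        arr = np.asarray(values)
        med = float(np.median(arr))
        mad = float(np.median(np.abs(arr - med)))
        if mad > 0:
            stats[g] = (med, mad)

    excluded: list[OutlierExclusion] = []
    out: list[DonationPayload] = []
    for p in payloads:
        kept = []
        for r in p.rows:
            g = (r.category, r.analyte)
            if g in stats:
                med, mad = stats[g]
                if abs(r.value - med) > k * mad:
                    excluded.append(OutlierExclusion(g, r, med, mad))
                    continue
            kept.append(r)
        out.append(DonationPayload(rows=tuple(kept), questionnaire=p.questionnaire))
    return out, excluded
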