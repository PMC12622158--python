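"""Support accounting and nS-mR consensus labeling.

The consensus rule: under criteria nS-mR a set of records is labeled ``pos``
only if it contains at least m positive records coming from at least n
distinct sources; it is labeled ``neg`` only if it contains no positive
record, at least m observed negative records, and negatives from at least n
distinct sources.  Anything else is ``excluded``.  The m-record clause counts
records pooled across sources, so 1S-5R means >=5 pos records with >=1
supporting source.

``unquantified`` records never count here; they enter only as default
negative votes during cluster voting (see :mod:`cysligand.clustering`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CysligandError
from .records import NEG, POS, CuratedDB, SiteRecord

EXCLUDED = "excluded"


@dataclass(frozen=True)
class ConsensusCriteria:
    """The nS-mR thresholds: >=m records from >=n distinct sources."""

    n_sources: int
    m_records: int

    def __post_init__(self):
        if self.n_sources < 1 or self.m_records < 1:
            raise ValueError("criteria require n_sources >= 1 and m_records >= 1")

    @classmethod
    def parse(cls, text: str) -> "ConsensusCriteria":
        """Parse '4S-4R' (case-insensitive, '-' or '–')."""
        t = text.strip().upper().replace("–", "-")
        try:
            s_part, r_part = t.split("-")
            return cls(int(s_part.rstrip("S")), int(r_part.rstrip("R")))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse criteria {text!r}; expected 'nS-mR'") from exc

    def __str__(self) -> str:
        return f"{self.n_sources}S-{self.m_records}R"


@dataclass(frozen=True)
class SupportSummary:
    uid: str
    position: int
    n_quantifying_sources: int
    n_supporting_sources: int
    n_pos_records: int
    n_neg_records: int

    @property
    def liganded(self) -> bool:
        """At least one positive record anywhere."""
        return self.n_pos_records >= 1

    @property
    def p_supporting(self) -> float:
        """Fraction of quantifying sources that support (label positive)."""
        if self.n_quantifying_sources == 0:
            return float("nan")
        return self.n_supporting_sources / self.n_quantifying_sources


def summarize_support(db: CuratedDB) -> dict[tuple[str, int], SupportSummary]:
    """One :class:`SupportSummary` per observed site.

    Unquantified records do not count toward any source tally and sites with
    only unquantified records get no summary.
    """
    acc: dict[tuple[str, int], dict] = {}
    for r in db.records:
        if not r.observed:
            continue
        d = acc.setdefault(r.site, {"q": set(), "s": set(), "pos": 0, "neg": 0})
        d["q"].add(r.source_id)
        if r.label == POS:
            d["s"].add(r.source_id)
            d["pos"] += 1
        else:
            d["neg"] += 1
    return {
        site: SupportSummary(
            uid=site[0], position=site[1],
            n_quantifying_sources=len(d["q"]),
            n_supporting_sources=len(d["s"]),
            n_pos_records=d["pos"], n_neg_records=d["neg"],
        )
        for site, d in sorted(acc.items())
    }


def consensus_label(records: list[SiteRecord], criteria: ConsensusCriteria) -> str:
    """Apply the nS-mR rule to a pooled record set; returns pos/neg/excluded."""
    observed = [r for r in records if r.observed]
    if not observed:
        return EXCLUDED
    pos = [r for r in observed if r.label == POS]
    neg = [r for r in observed if r.label == NEG]
    pos_sources = {r.source_id for r in pos}
    neg_sources = {r.source_id for r in neg}
    if len(pos) >= criteria.m_records and len(pos_sources) >= criteria.n_sources:
        return POS
    if (not pos and len(neg) >= criteria.m_records
            and len(neg_sources) >= criteria.n_sources):
        return NEG
    return EXCLUDED


def binary_entropy_percent(p: float) -> float:
    """Shannon entropy of a Bernoulli(p) label distribution on a 0-100 scale.

    100 * (-p log2 p - (1-p) log2 (1-p)), with 0 log 0 := 0.
    """
    if not 0.0 <= p <= 1.0:
        raise CysligandError(f"p={p} outside [0, 1]")
    if p in (0.0, 1.0):
        return 0.0
    return float(100.0 * (-p * np.log2(p) - (1 - p) * np.log2(1 - p)))


@dataclass
class EntropyProfile:
    """Entropy distribution over sites quantified by at least n sources."""

    n: int
    count: int
    entropies: np.ndarray  # percent, one per qualifying site

    def quantiles(self, qs=(0.10, 0.50, 0.90)) -> tuple[float, ...]:
        if self.count == 0:
            return tuple(float("nan") for _ in qs)
        return tuple(float(np.quantile(self.entropies, q)) for q in qs)


def source_threshold_sweep(db: CuratedDB, n_values: list[int]) -> list[EntropyProfile]:
    """For each n: sites quantified by >= n sources, with their label entropy.

    p is the supporting/quantifying source fraction per site; entropy is the
    scaled binary entropy of p.
    """
    summaries = summarize_support(db)
    profiles = []
    for n in n_values:
        ent = [binary_entropy_percent(s.p_supporting)
               for s in summaries.values() if s.n_quantifying_sources >= n]
        profiles.append(EntropyProfile(n=n, count=len(ent), entropies=np.asarray(ent)))
    return profiles


@dataclass
class AccumulationCurve:
    criteria: ConsensusCriteria
    n_values: np.ndarray            # subset sizes 1..n_sources
    mean_norm_pos: np.ndarray       # mean positive count / naive total
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None


def positive_accumulation(
    db: CuratedDB,
    criteria_list: list[ConsensusCriteria],
    repeats: int = 200,
    rng_seed: int = 0,
) -> list[AccumulationCurve]:
    """Positive-label accumulation curves under random source subsampling.

    For each criteria and each subset size n, draw ``repeats`` random subsets
    of n sources, count sites labeled pos from the subset's records alone,
    and normalize by the naive total (sites with >=1 pos record anywhere).
    A normal-approximation 95% confidence band is attached to every curve
    (of interest mainly for the naive 1S-1R one).
    """
    observed = [r for r in db.records if r.observed]
    sources = sorted({r.source_id for r in observed})
    if not sources:
        raise CysligandError("database has no observed sources")
    naive_total = len({r.site for r in observed if r.label == POS})
    if naive_total == 0:
        raise CysligandError("database has no positive records")

    # per-site-per-source positive-record counts; the pos clause only needs
    # these (negatives cannot make a site pos)
    sites = sorted({r.site for r in observed})
    site_idx = {s: i for i, s in enumerate(sites)}
    src_idx = {s: i for i, s in enumerate(sources)}
    pos_counts = np.zeros((len(sites), len(sources)), dtype=np.int32)
    for r in observed:
        if r.label == POS:
            pos_counts[site_idx[r.site], src_idx[r.source_id]] += 1

    rng = np.random.default_rng(rng_seed)
    subset_draws = [
        [rng.choice(len(sources), size=n, replace=False) for _ in range(repeats)]
        for n in range(1, len(sources) + 1)
    ]

    curves = []
    for criteria in criteria_list:
        means, los, his = [], [], []
        for draws in subset_draws:
            counts = []
            for subset in draws:
                sub = pos_counts[:, subset]
                is_pos = ((sub.sum(axis=1) >= criteria.m_records)
                          & ((sub > 0).sum(axis=1) >= criteria.n_sources))
                counts.append(int(is_pos.sum()) / naive_total)
            arr = np.asarray(counts)
            m = float(arr.mean())
            half = 1.96 * float(arr.std(ddof=1)) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
            means.append(m)
            los.append(m - half)
            his.append(m + half)
        curves.append(AccumulationCurve(
            criteria=criteria,
            n_values=np.arange(1, len(sources) + 1),
            mean_norm_pos=np.asarray(means),
            ci_low=np.asarray(los), ci_high=np.asarray(his),
        ))
    return curves


__all__ = [
    "EXCLUDED", "ConsensusCriteria", "SupportSummary", "EntropyProfile",
    "AccumulationCurve", "summarize_support", "consensus_label",
    "binary_entropy_percent", "source_threshold_sweep", "positive_accumulation",
]
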