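"""Iterative training-data expansion protocols.

Two acceptance-gated ways of growing a high-confidence baseline training set
from a larger pool of candidate labeled sites:

* **external-recovery guided** (:func:`lc3d_guided_expand`): per iteration,
  sample random candidate batches, score each by the Top-1 recovery of a
  screening ensemble trained on baseline+batch against a fixed external
  evaluation set, revalidate the best batch with a larger ensemble, and
  accept only if the revalidated Top-1 beats the running baseline.  The
  first non-accepting iteration ends the protocol.

* **cross-validation guided** (:func:`abpp_guided_expand`): batches of fixed
  composition (25 positives, remainder negatives) are assembled with
  preference for high ensemble-uncertainty candidates and compete in
  tournaments: each tournament runs a few iterations of evaluate / keep top
  performers / breed crossover and mutation variants, and a batch is
  admitted only when its cross-validated AUPRC enrichment (PRCE) exceeds
  the baseline's by more than one standard error across folds.  The
  protocol stops after a full tournament without any acceptance.

Both protocols enforce the leakage rules (candidates never share uids with
the evaluation material) and log every evaluated batch into a replayable
history keyed off a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._hash import rng_for, stable_u31
from .clustering import _uid_components
from .errors import ContractError, DegenerateDataError
from .metrics import auprc, prce, top_k_recovery
from .models import (EnsembleSpec, HeadConfig, LabeledSite,
                     _clusters_from_sites, train_ensemble, train_head)

Site = tuple[str, int]


@dataclass
class EvalSet:
    """A fixed evaluation set: sites, binary labels, embedding vectors."""

    labels: dict[Site, int]
    vectors: dict[Site, np.ndarray]

    @property
    def sites(self) -> list[Site]:
        return sorted(self.labels)

    @property
    def uids(self) -> set[str]:
        return {uid for uid, _ in self.labels}


@dataclass
class ExpansionHistory:
    iterations: list[dict] = field(default_factory=list)
    batches: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def accepted_metrics(self) -> list[float]:
        return [it["metric"] for it in self.iterations if it["accepted"]]

    def to_jsonl(self) -> str:
        import json
        lines = [json.dumps({"kind": "note", "text": n}) for n in self.notes]
        lines += [json.dumps({"kind": "batch", **b}, sort_keys=True)
                  for b in self.batches]
        lines += [json.dumps({"kind": "iteration", **it}, sort_keys=True)
                  for it in self.iterations]
        return "\n".join(lines) + "\n"


def _site_ids(sites: list[LabeledSite]) -> list[str]:
    return [f"{s.uid}:{s.position}" for s in sites]


def _check_disjoint(pool: list[LabeledSite], baseline: list[LabeledSite],
                    eval_set: EvalSet) -> None:
    pool_sites = {s.site for s in pool}
    if pool_sites & {s.site for s in baseline}:
        raise ContractError("candidate pool overlaps the baseline training set")
    if {u for u, _ in pool_sites} & eval_set.uids:
        raise ContractError("candidate pool shares uids with the evaluation set")
    if {s.uid for s in baseline} & eval_set.uids:
        raise ContractError("baseline shares uids with the evaluation set")


def _top1(train_sites: list[LabeledSite], eval_set: EvalSet,
          spec: EnsembleSpec, config: HeadConfig, seed: int) -> float:
    ens = train_ensemble(train_sites, spec, config, seed=seed)
    pred = ens.predict(eval_set.sites, eval_set.vectors)
    return top_k_recovery(pred, eval_set.labels, k=1)


def lc3d_guided_expand(
    baseline: list[LabeledSite],
    pool: list[LabeledSite],
    eval_set: EvalSet,
    config: HeadConfig,
    rng_seed: int = 0,
    schedule: tuple[int, ...] = (80, 100, 150, 175),
    n_batches: int = 100,
    screen_spec: EnsembleSpec = EnsembleSpec(6, 4),
    reval_spec: EnsembleSpec = EnsembleSpec(10, 20),
    max_iterations: int | None = None,
) -> tuple[list[LabeledSite], ExpansionHistory]:
    """Random-batch expansion gated by external Top-1 recovery.

    The iteration batch size follows ``schedule`` (the last entry repeats).
    Stops at the first iteration whose revalidated best batch fails to beat
    the previous accepted baseline, when the pool runs dry, or after
    ``max_iterations``.
    """
    _check_disjoint(pool, baseline, eval_set)
    history = ExpansionHistory()
    current = list(baseline)
    remaining = sorted(pool, key=lambda s: s.site)
    baseline_metric = _top1(current, eval_set, reval_spec, config,
                            stable_u31(rng_seed, "baseline"))
    history.notes.append(f"baseline top1={baseline_metric:.4f}")

    it = 0
    while max_iterations is None or it < max_iterations:
        if not remaining:
            history.notes.append("pool exhausted; terminating normally")
            break
        size = schedule[min(it, len(schedule) - 1)]
        size = min(size, len(remaining))
        rng = rng_for(rng_seed, "batches", it)
        candidates = [sorted(rng.choice(len(remaining), size=size, replace=False))
                      for _ in range(n_batches)]
        scores = []
        for b, idx in enumerate(candidates):
            batch = [remaining[i] for i in idx]
            t1 = _top1(current + batch, eval_set, screen_spec, config,
                       stable_u31(rng_seed, "screen", it, b))
            scores.append(t1)
            history.batches.append({
                "protocol": "lc3d", "iteration": it, "batch": b,
                "size": size, "members": _site_ids(batch), "top1_screen": t1,
            })
        best = int(np.argmax(scores))
        best_batch = [remaining[i] for i in candidates[best]]
        reval = _top1(current + best_batch, eval_set, reval_spec, config,
                      stable_u31(rng_seed, "reval", it))
        accepted = reval > baseline_metric
        history.iterations.append({
            "protocol": "lc3d", "iteration": it, "batch_size": size,
            "best_batch": best, "metric": reval, "previous": baseline_metric,
            "accepted": accepted,
            "train_size_before": len(current),
            "train_size_after": len(current) + (len(best_batch) if accepted else 0),
        })
        if not accepted:
            break
        chosen = set(candidates[best])
        current = current + best_batch
        remaining = [s for i, s in enumerate(remaining) if i not in chosen]
        baseline_metric = reval
        it += 1
    return current, history


# ---------------------------------------------------------------------------
# cross-validation guided protocol

@dataclass(frozen=True)
class GAConfig:
    survivors: int = 4
    n_crossover: int = 4
    n_mutation: int = 4
    mutation_frac: float = 0.10


def _fold_assignment(sites: list[LabeledSite], k: int, seed: int) -> list[int]:
    """Fold index per site; uid-connected cluster components stay together."""
    clusters, by_index = _clusters_from_sites(sites)
    comps = _uid_components(clusters)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(comps)))
    order.sort(key=lambda c: -sum(len(by_index[i]) for i in comps[c]))
    fill = [0] * k
    fold_of_cluster: dict[int, int] = {}
    for ci in order:
        f = int(np.argmin(fill))
        for i in comps[ci]:
            fold_of_cluster[i] = f
            fill[f] += len(by_index[i])
    site_fold: dict[Site, int] = {}
    for i, lss in by_index.items():
        for ls in lss:
            site_fold[ls.site] = fold_of_cluster[i]
    return [site_fold[s.site] for s in sites]


def cv_prce(sites: list[LabeledSite], config: HeadConfig, k: int = 4,
            seed: int = 0) -> tuple[float, float, list[float]]:
    """Cross-validated PRCE: mean, standard error, and per-fold values.

    Folds respect cluster/uid grouping.  Folds that end up single-class on
    either side are skipped; at least two usable folds are required.
    """
    folds = _fold_assignment(sites, k, seed)
    values = []
    for f in range(k):
        train = [s for s, ff in zip(sites, folds) if ff != f]
        test = [s for s, ff in zip(sites, folds) if ff == f]
        y_tr = {s.label for s in train}
        y_te = [s.label for s in test]
        if len(y_tr) < 2 or len(set(y_te)) < 2:
            continue
        head = train_head(np.asarray([s.vector for s in train]),
                          np.asarray([s.label for s in train]),
                          replace(config, seed=stable_u31(seed, "cv", f)))
        scores = head.predict_proba(np.asarray([s.vector for s in test]))
        values.append(prce(auprc(scores, y_te), float(np.mean(y_te))))
    if len(values) < 2:
        raise DegenerateDataError("fewer than two usable CV folds")
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr))), values


@dataclass(frozen=True)
class _Batch:
    pos: tuple[Site, ...]
    neg: tuple[Site, ...]
    kind: str = "fresh"

    @property
    def members(self) -> tuple[Site, ...]:
        return tuple(sorted(self.pos + self.neg))


def _crossover(a: _Batch, b: _Batch, rng) -> _Batch:
    """Swap random same-class member subsets between two batches.

    Composition is preserved exactly: only elements unique to each parent
    are exchanged, in equal numbers per class.
    """
    def swap(xa: tuple, xb: tuple) -> tuple:
        only_a = sorted(set(xa) - set(xb))
        only_b = sorted(set(xb) - set(xa))
        m = min(len(only_a), len(only_b))
        if m == 0:
            return xa
        n_swap = int(rng.integers(1, m + 1))
        out_a = set(xa) - set(rng_sample(rng, only_a, n_swap))
        out_a |= set(rng_sample(rng, only_b, n_swap))
        return tuple(sorted(out_a))

    return _Batch(pos=swap(a.pos, b.pos), neg=swap(a.neg, b.neg), kind="crossover")


def _mutate(batch: _Batch, pool_pos: list[Site], pool_neg: list[Site],
            frac: float, rng) -> _Batch:
    """Replace ~frac of each class with unused pool members of that class."""
    def sub(members: tuple, candidates: list[Site]) -> tuple:
        avail = sorted(set(candidates) - set(members))
        n = min(max(1, round(frac * len(members))), len(avail), len(members))
        if n == 0:
            return members
        drop = set(rng_sample(rng, sorted(members), n))
        add = set(rng_sample(rng, avail, n))
        return tuple(sorted((set(members) - drop) | add))

    return _Batch(pos=sub(batch.pos, pool_pos), neg=sub(batch.neg, pool_neg),
                  kind="mutation")


def rng_sample(rng, seq: list, n: int) -> list:
    idx = rng.choice(len(seq), size=n, replace=False)
    return [seq[i] for i in idx]


def abpp_guided_expand(
    baseline: list[LabeledSite],
    pool: list[LabeledSite],
    config: HeadConfig,
    rng_seed: int = 0,
    cv_folds: int = 4,
    n_pos_per_batch: int = 25,
    batch_size_early: int = 100,
    batch_size_late: int = 175,
    late_from_tournament: int = 3,
    n_batches: int = 20,
    tournaments: int = 4,
    iterations_per_tournament: int = 4,
    ga: GAConfig = GAConfig(),
    uncertainty_spec: EnsembleSpec = EnsembleSpec(2, 2),
    eval_set: EvalSet | None = None,
) -> tuple[list[LabeledSite], ExpansionHistory]:
    """Tournament expansion gated by cross-validated PRCE.

    Acceptance requires the candidate's CV PRCE to exceed the baseline's by
    more than one standard error of the baseline's across-fold PRCE.  If
    ``eval_set`` is given it is only used for leakage checking of pool/
    baseline uids (never for selection).
    """
    if eval_set is not None:
        _check_disjoint(pool, baseline, eval_set)
    history = ExpansionHistory()
    by_site = {s.site: s for s in pool}
    pool_pos = sorted(s.site for s in pool if s.label == 1)
    pool_neg = sorted(s.site for s in pool if s.label == 0)
    if len(pool_pos) < n_pos_per_batch:
        history.notes.append(
            f"composition error: pool has {len(pool_pos)} positives, "
            f"needs {n_pos_per_batch}; protocol halted")
        return list(baseline), history

    current = list(baseline)
    base_mean, base_se, _ = cv_prce(current, config, cv_folds,
                                    stable_u31(rng_seed, "cv0"))
    history.notes.append(f"baseline prce={base_mean:.2f} se={base_se:.2f}")
    last_accepted = -np.inf  # accepted metrics must strictly increase

    def batch_sites(batch: _Batch) -> list[LabeledSite]:
        return [by_site[s] for s in batch.members]

    def uncertainty_weights(candidates: list[Site], seed: int) -> np.ndarray:
        if not candidates:
            return np.asarray([])
        try:
            ens = train_ensemble(current, uncertainty_spec, config, seed=seed)
            unc = ens.uncertainty(candidates, {s: by_site[s].vector
                                               for s in candidates})
            w = np.asarray([unc[s] for s in candidates]) + 1e-6
        except DegenerateDataError:
            w = np.ones(len(candidates))
        return w / w.sum()

    it_global = 0
    for tour in range(1, tournaments + 1):
        size = batch_size_early if tour < late_from_tournament else batch_size_late
        size = min(size, len(pool_pos) + len(pool_neg))
        n_neg = max(0, size - n_pos_per_batch)
        accepted_in_tournament = 0
        rng = rng_for(rng_seed, "tour", tour)
        w_pos = uncertainty_weights(pool_pos, stable_u31(rng_seed, "unc", tour, 0))
        w_neg = uncertainty_weights(pool_neg, stable_u31(rng_seed, "unc", tour, 1))
        population: list[_Batch] = []
        for _ in range(n_batches):
            if len(pool_pos) < n_pos_per_batch or len(pool_neg) < n_neg:
                break
            p_idx = rng.choice(len(pool_pos), size=n_pos_per_batch,
                               replace=False, p=w_pos)
            n_idx = rng.choice(len(pool_neg), size=n_neg, replace=False, p=w_neg)
            population.append(_Batch(
                pos=tuple(sorted(pool_pos[i] for i in p_idx)),
                neg=tuple(sorted(pool_neg[i] for i in n_idx))))
        if not population:
            history.notes.append("pool exhausted; terminating")
            break

        for it in range(1, iterations_per_tournament + 1):
            it_global += 1
            evaluated = []
            for b, batch in enumerate(population):
                mean, se, _ = cv_prce(current + batch_sites(batch), config,
                                      cv_folds,
                                      stable_u31(rng_seed, "cv", tour, it, b))
                evaluated.append((mean, se, batch))
                history.batches.append({
                    "protocol": "abpp", "tournament": tour, "iteration": it,
                    "batch": b, "kind": batch.kind, "size": len(batch.members),
                    "n_pos": len(batch.pos),
                    "members": [f"{u}:{p}" for u, p in batch.members],
                    "prce_mean": mean, "prce_se": se,
                })
            evaluated.sort(key=lambda t: -t[0])
            best_mean, best_se, best_batch = evaluated[0]
            accepted = (best_mean > base_mean + base_se
                        and best_mean > last_accepted)
            history.iterations.append({
                "protocol": "abpp", "tournament": tour, "iteration": it,
                "metric": best_mean, "previous": base_mean,
                "previous_se": base_se, "accepted": accepted,
                "n_variants": sum(1 for *_, bb in evaluated
                                  if bb.kind in ("crossover", "mutation")),
                "train_size_before": len(current),
                "train_size_after": len(current) + (len(best_batch.members)
                                                    if accepted else 0),
            })
            if accepted:
                last_accepted = best_mean
                current = current + batch_sites(best_batch)
                taken = set(best_batch.members)
                pool_pos = [s for s in pool_pos if s not in taken]
                pool_neg = [s for s in pool_neg if s not in taken]
                base_mean, base_se, _ = cv_prce(
                    current, config, cv_folds,
                    stable_u31(rng_seed, "cvb", tour, it))
                accepted_in_tournament += 1

            # breed the next generation from the survivors
            taken = set(best_batch.members) if accepted else set()
            survivors = [bb for *_, bb in evaluated
                         if not (set(bb.members) & taken)][:ga.survivors]
            next_pop = [(_Batch(bb.pos, bb.neg, kind="survivor"))
                        for bb in survivors]
            for c in range(ga.n_crossover):
                if len(survivors) >= 2:
                    i, j = rng_sample(rng, list(range(len(survivors))), 2)
                    next_pop.append(_crossover(survivors[i], survivors[j], rng))
            for m in range(ga.n_mutation):
                if survivors:
                    parent = survivors[int(rng.integers(len(survivors)))]
                    next_pop.append(_mutate(parent, pool_pos, pool_neg,
                                            ga.mutation_frac, rng))
            population = [bb for bb in next_pop
                          if len(bb.pos) == n_pos_per_batch
                          and not (set(bb.members) & taken)]
            if not population:
                break
        if accepted_in_tournament == 0:
            history.notes.append(f"tournament {tour} accepted nothing; terminating")
            break
    return current, history


__all__ = [
    "EvalSet", "ExpansionHistory", "GAConfig",
    "lc3d_guided_expand", "abpp_guided_expand", "cv_prce",
]
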