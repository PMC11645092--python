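"""Self-influence dataset distillation experiments.

The experiment grid retrains the classifier on three kinds of training sets —
the full set (FT), the subset that survives removal of the highest
self-influence samples (SIST), and a random subset of identical size (RST) —
at matched usage tiers (default 77%, 67%, 50% of the training data), averaged
over r seeded runs, always evaluating on one shared, untouched test split.
Category-level attribution aggregates pairwise influence over the stimulus
category of each training image.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import MetricsReport
from .model import GBACConfig, build_model, desk_config, prepare_records, slice_batch
from .synth import SyntheticSpec, build_dataset
from .tracin import InfluenceTable, influence_table, rank_self_influence, self_influence_table
from .train import evaluate, split_dataset, train
from .types import ASD, SampleRecord


@dataclass
class ExperimentPlan:
    """The grid: usage tiers x {FT, SIST, RST} x r seeded runs, one shared test split."""

    usage_tiers: tuple[float, ...] = (0.77, 0.67, 0.50)
    runs: int = 5
    seeds: Optional[Sequence[int]] = None
    split_seed: int = 12345
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    participant_disjoint: bool = False
    gradient_mode: str = "last_layer"
    # checkpoints used for the self-influence ranking: "all", or "first_half"
    # (before a small model starts memorizing outliers, their gradients are
    # largest; late checkpoints can mute exactly the samples SIST should drop)
    ranking_checkpoints: str = "all"
    fixed_subset_from_first_seed: bool = False  # ablation: reuse seed-0 SIST subset

    def __post_init__(self) -> None:
        for f in self.usage_tiers:
            if not 0.0 < f <= 1.0:
                raise ValueError(f"usage fraction {f} out of (0, 1]")
        if self.seeds is None:
            self.seeds = [1000 + 7 * i for i in range(self.runs)]
        if len(self.seeds) != self.runs:
            raise ValueError("need exactly one seed per run")
        if self.ranking_checkpoints not in ("all", "first_half"):
            raise ValueError(f"unknown ranking_checkpoints {self.ranking_checkpoints!r}")


def _n_keep(n: int, fraction: float) -> int:
    return int(np.floor(fraction * n + 0.5))


def filter_by_self_influence(
    train_set: Sequence[SampleRecord],
    ranking: Sequence[tuple[str, float]],
    usage_fraction: float,
) -> list[SampleRecord]:
    """Drop the highest-self-influence samples, keeping round(fraction * N).

    ``ranking`` is the descending (sample_id, score) list over the training
    set; removal proceeds from its top.  The retained subset keeps the
    original training-set order.
    """
    if not 0.0 < usage_fraction <= 1.0:
        raise ValueError(f"usage fraction {usage_fraction} out of (0, 1]")
    ids = {r.sample_id for r in train_set}
    ranked_ids = [sid for sid, _ in ranking]
    if set(ranked_ids) != ids:
        raise ValueError("ranking does not cover the training set exactly")
    n_keep = _n_keep(len(train_set), usage_fraction)
    removed = set(ranked_ids[: len(train_set) - n_keep])
    return [r for r in train_set if r.sample_id not in removed]


def random_subset(
    train_set: Sequence[SampleRecord],
    usage_fraction: float,
    seed: int,
    size: Optional[int] = None,
) -> list[SampleRecord]:
    """Uniform subset without replacement, matched in size to the SIST tier."""
    if not 0.0 < usage_fraction <= 1.0:
        raise ValueError(f"usage fraction {usage_fraction} out of (0, 1]")
    n_keep = size if size is not None else _n_keep(len(train_set), usage_fraction)
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(train_set), size=n_keep, replace=False).tolist())
    return [r for i, r in enumerate(train_set) if i in chosen]


def _test_split_hash(prepared_test: dict) -> str:
    return hashlib.sha256("|".join(prepared_test["sample_ids"]).encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    table: pd.DataFrame  # one row per variant x tier, averaged over runs
    per_run: pd.DataFrame  # one row per variant x tier x seed
    test_split_hash: str
    seeds: list[int] = field(default_factory=list)

    def row(self, variant: str, tier: int = 0) -> pd.Series:
        m = (self.table["variant"] == variant) & (self.table["tier"] == tier)
        return self.table[m].iloc[0]


def _metrics_row(report: MetricsReport, variant: str, tier: int, usage: float, seed: int) -> dict:
    return {
        "variant": variant,
        "tier": tier,
        "dataset_usage": usage,
        "seed": seed,
        "accuracy": report.accuracy,
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "n_test": report.n,
    }


def run_experiment(
    plan: ExperimentPlan,
    records: Sequence[SampleRecord],
    config: GBACConfig,
) -> ExperimentResult:
    """Run the FT / SIST / RST grid and return averaged metrics.

    Per seed: train FT on the shared training split, score self-influence
    from the FT checkpoints, build the SIST and (size-matched) RST subsets at
    each tier, retrain, and evaluate everything on the one shared test split.
    Tier index 0 is the FT row; SIST/RST tiers are numbered from 1 in the
    order of ``plan.usage_tiers``.
    """
    train_recs, val_recs, test_recs = split_dataset(
        records,
        plan.split_seed,
        fractions=plan.split_fractions,
        participant_disjoint=plan.participant_disjoint,
    )
    prep_train = prepare_records(train_recs, config)
    prep_val = prepare_records(val_recs, config)
    prep_test = prepare_records(test_recs, config)
    split_hash = _test_split_hash(prep_test)
    id_to_idx = {sid: i for i, sid in enumerate(prep_train["sample_ids"])}

    rows = []
    first_seed_subsets: dict[int, list[str]] = {}
    stage = "setup"
    try:
        for seed in plan.seeds:
            stage = f"FT training (seed {seed})"
            model = build_model(config, seed=seed)
            ckpts, _hist = train(model, prep_train, config, seed=seed, val_records=prep_val)
            rows.append(_metrics_row(evaluate(model, prep_test, config), "FT", 0, 1.0, seed))

            stage = f"self-influence ranking (seed {seed})"
            if plan.ranking_checkpoints == "first_half":
                from .train import CheckpointSet

                rank_ckpts = CheckpointSet(ckpts.checkpoints[: max(1, ckpts.k // 2)], seed=ckpts.seed)
            else:
                rank_ckpts = ckpts
            ranking = rank_self_influence(rank_ckpts, model, prep_train, mode=plan.gradient_mode)
            for t, fraction in enumerate(plan.usage_tiers, start=1):
                stage = f"tier {t} retraining (seed {seed})"
                if plan.fixed_subset_from_first_seed and t in first_seed_subsets:
                    keep_ids = first_seed_subsets[t]
                    sist = [r for r in train_recs if r.sample_id in set(keep_ids)]
                else:
                    sist = filter_by_self_influence(train_recs, ranking, fraction)
                    if plan.fixed_subset_from_first_seed:
                        first_seed_subsets[t] = [r.sample_id for r in sist]
                rst = random_subset(train_recs, fraction, seed=seed * 131 + t, size=len(sist))
                assert len(sist) == len(rst)
                for variant, subset in (("SIST", sist), ("RST", rst)):
                    idx = np.array([id_to_idx[r.sample_id] for r in subset])
                    sub_prep = slice_batch(prep_train, idx)
                    sub_model = build_model(config, seed=seed)
                    train(sub_model, sub_prep, config, seed=seed, val_records=prep_val)
                    rows.append(
                        _metrics_row(evaluate(sub_model, prep_test, config), variant, t, fraction, seed)
                    )
    except Exception as exc:
        err = RuntimeError(f"experiment failed at stage: {stage}")
        err.partial_results = pd.DataFrame(rows)  # completed rows survive
        raise err from exc

    per_run = pd.DataFrame(rows)
    agg = (
        per_run.groupby(["variant", "tier", "dataset_usage"], as_index=False)
        .agg(
            accuracy=("accuracy", "mean"),
            accuracy_std=("accuracy", "std"),
            precision=("precision", "mean"),
            recall=("recall", "mean"),
            f1=("f1", "mean"),
            f1_std=("f1", "std"),
        )
        .sort_values(["tier", "variant"])
        .reset_index(drop=True)
    )
    return ExperimentResult(agg, per_run, split_hash, seeds=list(plan.seeds))


def aggregate_influence_by_category(
    pairwise: InfluenceTable,
    categories: Mapping[str, str],
    top_m: int = 3,
    proponent_depth: int = 10,
) -> pd.DataFrame:
    """Rank stimulus categories by the mean influence of their training samples.

    ``pairwise`` must hold train-by-test influence for the test samples of
    interest (e.g. correctly classified ASD samples).  Categories are ranked
    by the *signed* mean influence: gradient noise produces large influence
    entries of both signs that cancel in the mean, while systematic support
    for correct classification survives, so the signed mean isolates the
    categories the network genuinely learned from (a positive-part mean
    would reward high-variance noise instead).  The positive-part mean is
    still reported, along with the ``top_m`` training images of each
    category that appear most often among each test sample's
    ``proponent_depth`` strongest proponents.  Unknown image ids fall into
    "other".
    """
    M = pairwise.pairwise
    if M is None:
        raise ValueError("pairwise influence table required")
    train_ids = list(M.index)
    image_of = {sid: sid.rsplit(":", 2)[0] for sid in train_ids}
    cat_of = {sid: categories.get(image_of[sid], "other") for sid in train_ids}

    proponent_hits: Counter = Counter()
    for col in M.columns:
        top = M[col].sort_values(ascending=False).head(proponent_depth)
        proponent_hits.update(image_of[sid] for sid in top.index[top.values > 0])

    rows = []
    for cat in sorted(set(cat_of.values())):
        sids = [sid for sid in train_ids if cat_of[sid] == cat]
        vals = M.loc[sids].values.ravel()
        pos = vals[vals > 0]
        images = sorted({image_of[sid] for sid in sids})
        top_images = sorted(images, key=lambda im: (-proponent_hits[im], im))[:top_m]
        rows.append(
            {
                "category": cat,
                "mean_influence": float(vals.mean()) if vals.size else 0.0,
                "mean_positive_influence": float(pos.mean()) if pos.size else 0.0,
                "n_train_samples": len(sids),
                "top_proponent_images": ",".join(top_images),
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_influence", ascending=False)
    return out.reset_index(drop=True)


# -- composite synthetic experiments ---------------------------------------

#: Corpus for the label-noise experiments: all-people stimuli, so every record
#: carries the planted class signal.  Label noise is only meaningful where the
#: true label is predictable from the data; on signal-free (non-people) images
#: a flipped record is statistically identical to a clean one and the
#: experiment would measure image-memorization dynamics instead.
SIGNAL_CORPUS = {"category_mix": {"people": 1.0, "objects": 0.0, "landscapes": 0.0}}


def noisy_label_experiment(
    seeds: Sequence[int],
    config: GBACConfig | None = None,
    spec_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Can self-influence find planted label flips?

    Per seed: generate a corpus with 10% flipped labels, train on all of it,
    score self-influence from the checkpoints, and compare the mean
    self-influence percentile of flipped vs clean samples.  Returns one row
    per seed with the two means and whether flipped > clean.
    """
    config = config or desk_config()
    rows = []
    for seed in seeds:
        spec = SyntheticSpec(label_noise_rate=0.1, seed=seed, **(SIGNAL_CORPUS | (spec_kwargs or {})))
        records, truth = build_dataset(spec)
        prepared = prepare_records(records, config)
        model = build_model(config, seed=seed)
        ckpts, _ = train(model, prepared, config, seed=seed)
        table = self_influence_table(ckpts, model, prepared)
        scores = table.self_scores
        pct = scores.rank(pct=True) * 100.0
        flipped = set(truth["flipped_sample_ids"])
        is_flipped = pct.index.isin(flipped)
        rows.append(
            {
                "seed": seed,
                "n": len(scores),
                "n_flipped": int(is_flipped.sum()),
                "flipped_mean_percentile": float(pct[is_flipped].mean()),
                "clean_mean_percentile": float(pct[~is_flipped].mean()),
            }
        )
    df = pd.DataFrame(rows)
    df["recovered"] = df["flipped_mean_percentile"] > df["clean_mean_percentile"]
    return df


def sist_vs_rst_experiment(
    seeds: Sequence[int],
    config: GBACConfig | None = None,
    tier: float = 0.77,
    corpus_seed: int = 7,
    spec_kwargs: dict | None = None,
) -> ExperimentResult:
    """SIST vs RST on one noisy synthetic corpus at a single usage tier.

    A 60/10/30 split gives the comparison a larger shared test set than the
    training default, since the contrast of two means over r runs is what the
    experiment estimates.
    """
    config = config or desk_config()
    spec = SyntheticSpec(label_noise_rate=0.1, seed=corpus_seed, **(SIGNAL_CORPUS | (spec_kwargs or {})))
    records, _ = build_dataset(spec)
    plan = ExperimentPlan(
        usage_tiers=(tier,), runs=len(seeds), seeds=list(seeds),
        split_fractions=(0.6, 0.1, 0.3), split_seed=corpus_seed * 31 + 5,
        ranking_checkpoints="first_half",
    )
    return run_experiment(plan, records, config)


def category_attribution_experiment(
    seeds: Sequence[int],
    config: GBACConfig | None = None,
    spec_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Does attribution recover that only "people" images carry class signal?

    Per seed: generate a clean corpus, train on the training split, compute
    pairwise influence of training samples on the correctly classified ASD
    test samples, aggregate by category, and record the top-ranked category.
    """
    config = config or desk_config()
    rows = []
    for seed in seeds:
        spec = SyntheticSpec(seed=seed, **(spec_kwargs or {}))
        records, truth = build_dataset(spec)
        train_recs, val_recs, test_recs = split_dataset(records, seed=seed)
        prep_train = prepare_records(train_recs, config)
        prep_val = prepare_records(val_recs, config)
        model = build_model(config, seed=seed)
        ckpts, _ = train(model, prep_train, config, seed=seed, val_records=prep_val)

        prep_test = prepare_records(test_recs, config)
        from .nn import sigmoid
        from .train import forward_in_batches

        proba = sigmoid(forward_in_batches(model, prep_test, config.batch_size))
        correct_asd = np.where((prep_test["labels"] == ASD) & (proba >= 0.5))[0]
        if correct_asd.size == 0:
            rows.append({"seed": seed, "top_category": None, "n_test_targets": 0})
            continue
        targets = slice_batch(prep_test, correct_asd)
        table = influence_table(ckpts, model, prep_train, targets)
        ranked = aggregate_influence_by_category(table, truth["categories"])
        rows.append(
            {
                "seed": seed,
                "top_category": ranked.iloc[0]["category"],
                "n_test_targets": int(correct_asd.size),
                "mean_influence_people": float(
                    ranked.set_index("category")["mean_influence"].get("people", 0.0)
                ),
            }
        )
    return pd.DataFrame(rows)
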