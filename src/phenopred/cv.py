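"""CV1 / CV2 / CV3 cross-validation for multi-environment hybrid prediction.

Records are (hybrid, environment) BLUE cells.  Per repeat, hybrids are
split 70:30 into training and testing sets:

* CV1 — untested hybrids in characterized environments: test-hybrid
  records are masked in every environment; accuracy is the per-environment
  Pearson correlation over the 30 test hybrids.
* CV2 — tested hybrids in an uncharacterized environment: in addition to
  the CV1 mask, every record of one held-out environment is masked;
  accuracy is scored in the held-out environment over the 70 *training*
  hybrids.
* CV3 — untested hybrids in an uncharacterized environment: same masking
  as CV2, scored in the held-out environment over the 30 *test* hybrids.

With 100 hybrids and 8 environments this reproduces the canonical record
counts: 560 training / 240 testing (CV1) and 490 training / 310 masked
(CV2-CV3).  Model comparison uses Tukey's HSD on repeat-level accuracies
with a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .design import IncidenceMap
from .gibbs import ModelSpec, build_model, gibbs_fit

__all__ = [
    "CVPartition",
    "make_partitions",
    "score_partition",
    "run_scheme",
    "tukey_compare",
    "compact_letters",
]


@dataclass(frozen=True)
class CVPartition:
    """One repeat's hybrid split and masked-record bookkeeping."""

    scheme: str
    repeat: int
    train_hybrids: tuple[str, ...]
    test_hybrids: tuple[str, ...]
    held_out_env: str | None
    masked_records: tuple[tuple[str, str], ...]  # (hybrid, environment)

    def __post_init__(self) -> None:
        if set(self.train_hybrids) & set(self.test_hybrids):
            raise ValueError("train and test hybrid sets overlap")


def make_partitions(
    hybrids: list[str],
    environments: list[str],
    scheme: str,
    n_repeats: int = 50,
    held_out_env: str | None = None,
    seed: int | None = None,
    test_fraction: float = 0.3,
) -> list[CVPartition]:
    """Seeded 70:30 hybrid splits with per-scheme record masking."""
    scheme = scheme.upper()
    if scheme not in ("CV1", "CV2", "CV3"):
        raise ValueError("scheme must be CV1, CV2, or CV3")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if scheme in ("CV2", "CV3"):
        if held_out_env is None:
            raise ValueError(f"{scheme} requires held_out_env")
        if held_out_env not in environments:
            raise KeyError(f"held-out environment {held_out_env!r} not in design")
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(hybrids)))
    parts = []
    for rep in range(n_repeats):
        perm = rng.permutation(len(hybrids))
        test = tuple(hybrids[i] for i in sorted(perm[:n_test]))
        train = tuple(hybrids[i] for i in sorted(perm[n_test:]))
        masked = [(h, e) for h in test for e in environments]
        if scheme in ("CV2", "CV3"):
            masked = [(h, e) for h, e in masked if e != held_out_env]
            masked += [(h, held_out_env) for h in hybrids]
        parts.append(
            CVPartition(
                scheme=scheme,
                repeat=rep,
                train_hybrids=train,
                test_hybrids=test,
                held_out_env=held_out_env if scheme != "CV1" else None,
                masked_records=tuple(masked),
            )
        )
    return parts


def score_partition(
    predictions: pd.Series,
    partition: CVPartition,
    truth: pd.Series,
) -> pd.DataFrame:
    """Per-environment Pearson accuracies for one fitted partition.

    ``predictions`` and ``truth`` are indexed by (hybrid, environment).
    CV1 scores test hybrids in every environment; CV2 scores training
    hybrids in the held-out environment; CV3 scores test hybrids there.
    """
    missing = [r for r in partition.masked_records if r not in predictions.index]
    if missing:
        raise KeyError(f"predictions lack masked records, e.g. {missing[:3]}")
    if partition.scheme == "CV1":
        envs = sorted({e for _, e in partition.masked_records})
        cells = {e: [(h, e) for h in partition.test_hybrids] for e in envs}
    elif partition.scheme == "CV2":
        e = partition.held_out_env
        cells = {e: [(h, e) for h in partition.train_hybrids]}
    else:  # CV3
        e = partition.held_out_env
        cells = {e: [(h, e) for h in partition.test_hybrids]}
    rows = []
    for env, recs in cells.items():
        if len(recs) < 3:
            raise ValueError(f"fewer than 3 test records in environment {env!r}")
        p = predictions.loc[recs].to_numpy(dtype=float)
        t = truth.loc[recs].to_numpy(dtype=float)
        r = float(np.corrcoef(p, t)[0, 1])
        rows.append(
            {
                "scheme": partition.scheme,
                "repeat": partition.repeat,
                "environment": env,
                "r": r,
                "n_test": len(recs),
            }
        )
    return pd.DataFrame(rows)


def run_scheme(
    blues: pd.DataFrame,
    kernels: dict,
    models: dict[str, ModelSpec],
    scheme: str,
    n_repeats: int = 50,
    held_out_env: str | None = None,
    seed: int | None = None,
    response: str = "value",
) -> pd.DataFrame:
    """Fit every model on every partition and collect per-environment accuracy.

    ``blues`` is a long table with columns hybrid, environment, female,
    male, and the response (hybrid-by-environment BLUEs).  ``kernels``
    holds the entity-level inputs consumed by :func:`build_model`.
    Returns an accuracy table (scheme, repeat, environment, model, r,
    n_test).
    """
    frame = blues.reset_index(drop=True)
    incidence = IncidenceMap(
        frame, [c for c in ("female", "male", "hybrid", "environment") if c in frame]
    )
    hybrids = sorted(frame["hybrid"].unique())
    environments = sorted(frame["environment"].unique())
    rec_ids = list(zip(frame["hybrid"], frame["environment"]))
    truth = pd.Series(frame[response].to_numpy(dtype=float), index=rec_ids)
    parts = make_partitions(
        hybrids, environments, scheme, n_repeats, held_out_env, seed
    )
    ss = np.random.SeedSequence(seed)
    fit_seeds = ss.generate_state(n_repeats * len(models)) % 2**31
    stacks = {
        name: build_model(spec, kernels, incidence) for name, spec in models.items()
    }
    out = []
    for p_i, part in enumerate(parts):
        masked = set(part.masked_records)
        y = np.array(
            [
                np.nan if rid in masked else truth[rid]
                for rid in rec_ids
            ]
        )
        for m_i, (name, spec) in enumerate(models.items()):
            fit_spec = ModelSpec(
                model=spec.model,
                scope=spec.scope,
                n_iter=spec.n_iter,
                burn_in=spec.burn_in,
                thin=spec.thin,
                df0=spec.df0,
                r2=spec.r2,
                seed=int(fit_seeds[p_i * len(models) + m_i]),
            )
            fit = gibbs_fit(stacks[name], y, fit_spec, record_ids=rec_ids)
            preds = pd.Series(fit.fitted, index=rec_ids)
            scored = score_partition(preds, part, truth)
            scored["model"] = name
            out.append(scored)
    table = pd.concat(out, ignore_index=True)
    return table


def summarize_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE of accuracy per (scheme, model): environments averaged
    within repeat, SE across repeats."""
    per_rep = (
        table.groupby(["scheme", "model", "repeat"], observed=True)["r"]
        .mean()
        .reset_index()
    )
    agg = per_rep.groupby(["scheme", "model"], observed=True)["r"].agg(
        mean="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="count"
    )
    return agg.reset_index()


def compact_letters(groups: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups not sharing a letter differ.

    ``significant`` holds unordered pairs declared different.  Insertion
    algorithm: walk groups in order, try to place each into an existing
    letter class whose members it does not differ from.
    """
    classes: list[set[str]] = []
    for i, g in enumerate(groups):
        placed = False
        for cls in classes:
            if all(frozenset((g, other)) not in significant for other in cls):
                cls.add(g)
                placed = True
        if not placed:
            # insert-and-absorb: earlier compatible groups join the new class
            new = {g}
            for h in groups[:i]:
                if all(frozenset((h, other)) not in significant for other in new):
                    new.add(h)
            classes.append(new)
    letters = {g: "" for g in groups}
    for i, cls in enumerate(classes):
        for g in groups:
            if g in cls:
                letters[g] += chr(ord("a") + i)
    return letters


def tukey_compare(
    table: pd.DataFrame, grouping: str = "model", alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey HSD across models on repeat-level mean accuracies.

    Environments are averaged within repeat first, then the one-way Tukey
    honest-significant-difference test is applied with ``grouping`` as the
    only factor.  Returns per-group means with compact significance
    letters (groups sharing a letter do not differ at ``alpha``).
    """
    per_rep = (
        table.groupby([grouping, "repeat"], observed=True)["r"].mean().reset_index()
    )
    groups = per_rep[grouping].unique().tolist()
    if len(groups) < 2:
        raise ValueError("need >= 2 models to compare")
    if per_rep.groupby(grouping, observed=True)["r"].count().min() < 2:
        raise ValueError("need >= 2 repeats per model")
    if per_rep["r"].var(ddof=1) == 0:
        letters = {g: "a" for g in groups}
        res = None
    else:
        res = pairwise_tukeyhsd(per_rep["r"], per_rep[grouping], alpha=alpha)
        sig = set()
        frame = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        for _, row in frame.iterrows():
            if bool(row["reject"]):
                sig.add(frozenset((row["group1"], row["group2"])))
        order = (
            per_rep.groupby(grouping, observed=True)["r"].mean().sort_values(
                ascending=False
            )
        )
        letters = compact_letters(order.index.tolist(), sig)
    means = per_rep.groupby(grouping, observed=True)["r"].agg(["mean", "std", "count"])
    out = means.reset_index().rename(columns={"count": "n_repeats"})
    out["letter"] = out[grouping].map(letters)
    return out.sort_values("mean", ascending=False).reset_index(drop=True)
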