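"""End-to-end experiment: simulate -> preprocess -> split -> train the
three translation pairs -> translate all six directions -> classify.

The protocol enforces a three-way data separation per direction: the
translation model trains on the 90% partitions of both domains; the 10%
held-out originals of the *source* domain are the generation input; the
SVM trains on the 10% held-out originals of the *target* domain and is
tested on the generated data.  Baseline identification (the premise
check) trains on the 90% partition and tests on the 10% originals.

A single master seed fans out to per-stage seeds through
:func:`stage_seed`, so any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .classify import (ClassificationReport, SplitPlan, SvmSearchSpace,
                       evaluate, fit_svm, make_splits)
from .cyclegan import (TrainedPair, TrainingPlan, schedule_kind_for,
                       train_pair, translate_dataset)
from .networks import DiscriminatorSpec, GeneratorSpec
from .preprocess import (MovementVector, TrialDiscardedError,
                         locomotion_stride_vectors, preprocess_writing,
                         scale_unit_interval)
from .synthetic import (SPEED_FACTORS, WRITING_INSTRUCTIONS, make_domain_maps,
                        make_population, simulate_running_recording,
                        simulate_walking_recording, simulate_writing_trial)

__all__ = [
    "ExperimentConfig",
    "stage_seed",
    "simulate_trials",
    "export_raw_recordings",
    "preprocess_directory",
    "build_trials_table",
    "trials_from_table",
    "run_experiment",
    "plot_overlays",
]

log = logging.getLogger("crossmove")

PAIRS = (("walking", "running"), ("walking", "writing"),
         ("running", "writing"))

_STAGE_CODES = {"population": 1, "maps": 2, "simulate": 3, "split": 4,
                "gan": 5, "svm": 6}


def stage_seed(master: int, stage: str, *extra: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    state = np.random.SeedSequence(
        [master, _STAGE_CODES[stage], *extra]).generate_state(1)[0]
    return int(state) % (2 ** 31)


@dataclass
class ExperimentConfig:
    """Complete, validated description of one experiment run."""

    # population
    n_subjects: int = 17
    trials_per_domain: dict = field(default_factory=lambda: {
        "walking": 60, "running": 90, "writing": 55})
    sigma_trial: float = 0.3
    seed: int = 0
    # preprocessing
    locomotion_scaling: str = "global"   # or "per_trial"
    contact_threshold_n: float = 50.0
    # model
    generator: dict = field(default_factory=dict)       # GeneratorSpec overrides
    discriminator: dict = field(default_factory=dict)   # DiscriminatorSpec overrides
    training: dict = field(default_factory=dict)        # TrainingPlan overrides
    # protocol
    split: dict = field(default_factory=dict)           # SplitPlan overrides
    svm: dict = field(default_factory=dict)             # SvmSearchSpace overrides

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        missing = set(synthetic.DOMAINS) - set(self.trials_per_domain)
        if missing:
            raise ValueError(f"trials_per_domain missing {sorted(missing)}")
        if any(n < 2 for n in self.trials_per_domain.values()):
            raise ValueError("need at least 2 trials per subject per domain")
        if self.locomotion_scaling not in ("global", "per_trial"):
            raise ValueError("locomotion_scaling must be global or per_trial")
        if self.sigma_trial < 0 or self.contact_threshold_n <= 0:
            raise ValueError("noise scale and threshold must be positive")
        # fail early on unknown keys / bad values
        self.generator_spec()
        self.discriminator_spec()
        self.split_plan()
        self.svm_space()

    def generator_spec(self) -> GeneratorSpec:
        return GeneratorSpec(**self.generator)

    def discriminator_spec(self) -> DiscriminatorSpec:
        return DiscriminatorSpec(**self.discriminator)

    def training_plan(self, domain_a: str, domain_b: str) -> TrainingPlan:
        kwargs = dict(self.training)
        kwargs.setdefault("schedule_kind", schedule_kind_for(domain_a, domain_b))
        kwargs.setdefault("seed", stage_seed(
            self.seed, "gan", synthetic.hash_domain(domain_a),
            synthetic.hash_domain(domain_b)))
        return TrainingPlan(**kwargs)

    def split_plan(self) -> SplitPlan:
        kwargs = dict(self.split)
        kwargs.setdefault("seed", stage_seed(self.seed, "split"))
        return SplitPlan(**kwargs)

    def svm_space(self) -> SvmSearchSpace:
        return SvmSearchSpace(**self.svm)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self),
                                       sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Simulation + preprocessing into movement vectors

def simulate_trials(config: ExperimentConfig) -> dict[str, list[MovementVector]]:
    """Generate and preprocess the whole synthetic dataset.

    Locomotion recordings are simulated per subject and speed condition
    with as many strides as trials requested; each stride pair becomes
    one trial.  Writing trials cycle through the six instructions, half
    of them with the connected 'e'.  Locomotion vectors are scaled with
    the configured mode ('global' statistics come from the translation
    training partition, applied in :func:`run_experiment`; here global
    scaling is deferred by returning unscaled vectors internally).
    """
    subjects = make_population(config.n_subjects,
                               stage_seed(config.seed, "population"))
    maps = make_domain_maps(stage_seed(config.seed, "maps"),
                            sigma_trial=config.sigma_trial)
    simulators = {"walking": simulate_walking_recording,
                  "running": simulate_running_recording}

    unscaled: dict[str, list] = {d: [] for d in synthetic.DOMAINS}
    for subject in subjects:
        for domain in ("walking", "running"):
            n_total = config.trials_per_domain[domain]
            conditions = list(SPEED_FACTORS)
            base, rem = divmod(n_total, len(conditions))
            for ci, cond in enumerate(conditions):
                n_strides = base + (1 if ci < rem else 0)
                if n_strides == 0:
                    continue
                rec = simulators[domain](
                    subject, maps[domain], SPEED_FACTORS[cond],
                    n_strides=n_strides,
                    seed=stage_seed(config.seed, "simulate",
                                    subject.subject_id,
                                    synthetic.hash_domain(domain), ci))
                vectors = locomotion_stride_vectors(
                    rec, threshold=config.contact_threshold_n)
                if len(vectors) != n_strides:
                    raise RuntimeError(
                        f"simulate: expected {n_strides} stride pairs, got "
                        f"{len(vectors)} (subject {subject.subject_id}, "
                        f"{domain}/{cond})")
                for i, vec in enumerate(vectors):
                    trial_id = (f"s{subject.subject_id:03d}_{domain}_"
                                f"{cond}_t{i:03d}")
                    unscaled[domain].append((trial_id, subject.subject_id,
                                             cond, vec))
        n_write = config.trials_per_domain["writing"]
        for i in range(n_write):
            instruction = WRITING_INSTRUCTIONS[i % len(WRITING_INSTRUCTIONS)]
            trial_id = f"s{subject.subject_id:03d}_writing_t{i:03d}"
            # a trial whose W cannot be segmented is discarded and the
            # subject writes again (fresh seed)
            for attempt in range(8):
                rec = simulate_writing_trial(
                    subject, maps["writing"], instruction,
                    seed=stage_seed(config.seed, "simulate",
                                    subject.subject_id,
                                    synthetic.hash_domain("writing"),
                                    i, attempt),
                    attach_e=(i % 2 == 0))
                try:
                    vector = preprocess_writing(
                        rec, subject_id=subject.subject_id,
                        trial_id=trial_id)
                    break
                except TrialDiscardedError:
                    continue
            else:
                raise RuntimeError(
                    f"simulate: could not obtain a legible writing trial "
                    f"for subject {subject.subject_id}, trial {i}")
            unscaled["writing"].append(vector)

    return unscaled


def export_raw_recordings(config: ExperimentConfig, out_dir) -> int:
    """Write the raw synthetic recordings as delimited text + sidecars.

    One file pair per locomotion bout (subject x domain x speed) and per
    writing trial, self-described by sidecar metadata; the counterpart
    of :func:`simulate_trials` for workflows that start from raw files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = make_population(config.n_subjects,
                               stage_seed(config.seed, "population"))
    maps = make_domain_maps(stage_seed(config.seed, "maps"),
                            sigma_trial=config.sigma_trial)
    simulators = {"walking": simulate_walking_recording,
                  "running": simulate_running_recording}
    written = 0
    for subject in subjects:
        for domain in ("walking", "running"):
            n_total = config.trials_per_domain[domain]
            conditions = list(SPEED_FACTORS)
            base, rem = divmod(n_total, len(conditions))
            for ci, cond in enumerate(conditions):
                n_strides = base + (1 if ci < rem else 0)
                if n_strides == 0:
                    continue
                seed = stage_seed(config.seed, "simulate",
                                  subject.subject_id,
                                  synthetic.hash_domain(domain), ci)
                rec = simulators[domain](subject, maps[domain],
                                         SPEED_FACTORS[cond],
                                         n_strides=n_strides, seed=seed)
                synthetic.save_recording(
                    rec, out_dir / f"s{subject.subject_id:03d}_{domain}_{cond}",
                    subject_id=subject.subject_id, domain=domain, seed=seed)
                written += 1
        for i in range(config.trials_per_domain["writing"]):
            instruction = WRITING_INSTRUCTIONS[i % len(WRITING_INSTRUCTIONS)]
            seed = stage_seed(config.seed, "simulate", subject.subject_id,
                              synthetic.hash_domain("writing"), i, 0)
            rec = simulate_writing_trial(subject, maps["writing"],
                                         instruction, seed=seed,
                                         attach_e=(i % 2 == 0))
            synthetic.save_recording(
                rec, out_dir / f"s{subject.subject_id:03d}_writing_t{i:03d}",
                subject_id=subject.subject_id, domain="writing", seed=seed)
            written += 1
    return written


def preprocess_directory(raw_dir, threshold: float = 50.0,
                         scaling: str = "per_trial") -> list[MovementVector]:
    """Preprocess every saved recording in a directory into movement
    vectors (locomotion scaled per trial unless stated otherwise;
    illegible writing trials are skipped)."""
    raw_dir = Path(raw_dir)
    trials: list[MovementVector] = []
    from .preprocess import preprocess_locomotion
    for meta_path in sorted(raw_dir.glob("*.meta")):
        prefix = meta_path.with_suffix("")
        meta = synthetic.read_recording_meta(prefix)
        rec = synthetic.load_recording(prefix)
        subject_id = meta.get("subject_id")
        domain = meta.get("domain")
        if meta["kind"] == "force":
            trials.extend(preprocess_locomotion(
                rec, domain=domain, subject_id=subject_id,
                trial_id=prefix.name, threshold=threshold, scaling=scaling))
        else:
            try:
                trials.append(preprocess_writing(rec, subject_id=subject_id,
                                                 trial_id=prefix.name))
            except TrialDiscardedError as exc:
                log.warning("skipping %s: %s", prefix.name, exc)
    return trials


@dataclass
class _UnscaledTrial:
    """Locomotion stride vector before unit-interval scaling."""

    trial_id: str
    subject_id: int
    condition: str
    values: np.ndarray
    domain: str


def _wrap_unscaled(config, raw) -> dict[str, list]:
    out = {}
    for domain in synthetic.DOMAINS:
        if domain == "writing":
            out[domain] = raw[domain]
        else:
            out[domain] = [_UnscaledTrial(tid, sid, cond, vec, domain)
                           for tid, sid, cond, vec in raw[domain]]
    return out


def _scale_locomotion(trials, mode, gan_train_ids) -> list[MovementVector]:
    if mode == "global":
        train_vecs = [t.values for t in trials if t.trial_id in gan_train_ids]
        gmin = min(v.min() for v in train_vecs)
        gmax = max(v.max() for v in train_vecs)
    out = []
    for t in trials:
        if mode == "global":
            scaled = scale_unit_interval(t.values, "global",
                                         global_min=gmin, global_max=gmax)
        else:
            scaled = scale_unit_interval(t.values, "per_trial")
        out.append(MovementVector(values=scaled, domain=t.domain,
                                  subject_id=t.subject_id,
                                  condition=t.condition,
                                  source_trial_id=t.trial_id))
    return out


# ---------------------------------------------------------------------------
# Trials table (shared delimited-text exchange format)

_VALUE_COLS = [f"v{i:03d}" for i in range(256)]


def build_trials_table(trials: list[MovementVector]) -> pd.DataFrame:
    """Serialize movement vectors into the shared trials table."""
    rows = []
    for t in trials:
        row = {"trial_id": t.source_trial_id, "subject_id": t.subject_id,
               "domain": t.domain, "condition": t.condition,
               "origin": t.origin, "source_domain": t.source_domain}
        row.update(zip(_VALUE_COLS, t.values))
        rows.append(row)
    return pd.DataFrame(rows)


def trials_from_table(table: pd.DataFrame) -> list[MovementVector]:
    """Inverse of :func:`build_trials_table`."""
    missing = [c for c in _VALUE_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"trials table lacks {len(missing)} value columns")
    out = []
    for _, row in table.iterrows():
        source_domain = row.get("source_domain")
        if pd.isna(source_domain):
            source_domain = None
        out.append(MovementVector(
            values=row[_VALUE_COLS].to_numpy(dtype=float),
            domain=row["domain"], subject_id=row["subject_id"],
            condition=row["condition"], source_trial_id=row["trial_id"],
            origin=row.get("origin", "original"),
            source_domain=source_domain))
    return out


# ---------------------------------------------------------------------------
# Full experiment

def run_experiment(config: ExperimentConfig, out_dir,
                   progress: bool = False) -> pd.DataFrame:
    """Execute the full protocol and write reports under ``out_dir``.

    Returns the summary table: one row per baseline domain and one per
    translation direction, with accuracy, F1, precision, recall, ZRB,
    the F1/ZRB ratio and the train/test counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    stage = "simulate"
    try:
        raw = _wrap_unscaled(config, simulate_trials(config))

        stage = "split"
        split_plan = config.split_plan()
        splits = {d: make_splits(raw[d], split_plan)
                  for d in synthetic.DOMAINS}
        split_ids = {
            d: {part: sorted(_trial_id(t) for t in items)
                for part, items in splits[d].items()}
            for d in synthetic.DOMAINS}
        (out_dir / "splits.json").write_text(json.dumps(split_ids, indent=2))

        stage = "scale"
        data: dict[str, list[MovementVector]] = {}
        for domain in synthetic.DOMAINS:
            if domain == "writing":
                data[domain] = raw[domain]
            else:
                data[domain] = _scale_locomotion(
                    raw[domain], config.locomotion_scaling,
                    set(split_ids[domain]["gan_train"]))
        partition = {
            d: {part: [t for t in data[d]
                       if t.source_trial_id in set(split_ids[d][part])]
                for part in ("gan_train", "heldout")}
            for d in synthetic.DOMAINS}

        all_trials = [t for d in synthetic.DOMAINS for t in data[d]]
        reports: list[ClassificationReport] = []
        svm_space = config.svm_space()

        stage = "baseline-classification"
        for domain in synthetic.DOMAINS:
            train = partition[domain]["gan_train"]
            test = partition[domain]["heldout"]
            model, chosen = fit_svm(
                train, svm_space,
                seed=stage_seed(config.seed, "svm",
                                synthetic.hash_domain(domain)))
            rep = evaluate(model, test, [t.subject_id for t in train],
                           task=f"baseline_{domain}", chosen=chosen)
            rep.save(out_dir / f"report_baseline_{domain}.json")
            reports.append(rep)
            log.info("baseline %s: F1=%.1f%% (ZRB %.1f%%)", domain, rep.f1,
                     rep.zrb)

        stage = "train-gan"
        pairs: dict[tuple[str, str], TrainedPair] = {}
        for domain_a, domain_b in PAIRS:
            plan = config.training_plan(domain_a, domain_b)
            pair = train_pair(partition[domain_a]["gan_train"],
                              partition[domain_b]["gan_train"], plan,
                              config.generator_spec(),
                              config.discriminator_spec(),
                              progress=progress)
            pair.loss_log.to_csv(
                out_dir / f"loss_{domain_a}_{domain_b}.csv", index=False)
            pairs[(domain_a, domain_b)] = pair
            log.info("trained %s<->%s (selected epoch %d)", domain_a,
                     domain_b, pair.selected_epoch)

        stage = "translate+classify"
        for domain_a, domain_b in PAIRS:
            pair = pairs[(domain_a, domain_b)]
            for source, target, gen in ((domain_a, domain_b, pair.G),
                                        (domain_b, domain_a, pair.F)):
                generated = translate_dataset(gen,
                                              partition[source]["heldout"])
                all_trials.extend(generated)
                train = partition[target]["heldout"]
                model, chosen = fit_svm(
                    train, svm_space,
                    seed=stage_seed(config.seed, "svm",
                                    synthetic.hash_domain(source),
                                    synthetic.hash_domain(target)))
                rep = evaluate(model, generated,
                               [t.subject_id for t in train],
                               task=f"gen_{target}_from_{source}",
                               chosen=chosen)
                rep.save(out_dir / f"report_gen_{target}_from_{source}.json")
                reports.append(rep)
                log.info("gen %s from %s: F1=%.1f%% (ZRB %.1f%%)", target,
                         source, rep.f1, rep.zrb)

        stage = "report"
        build_trials_table(all_trials).to_csv(out_dir / "trials.csv",
                                              index=False)
        summary = summarize(reports)
        summary.to_csv(out_dir / "summary.csv", index=False)
        return summary
    except Exception:
        log.exception("experiment failed in stage %r", stage)
        raise


def _trial_id(t) -> str:
    return t.trial_id if hasattr(t, "trial_id") else t.source_trial_id


def summarize(reports: list[ClassificationReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        if rep.task.startswith("baseline_"):
            test_data, generated_from = rep.task.split("_", 1)[1], None
        else:
            _, target, _, source = rep.task.split("_")
            test_data, generated_from = f"gen_{target}", source
        rows.append({
            "task": rep.task, "test_data": test_data,
            "generated_from": generated_from,
            "accuracy": rep.accuracy, "f1": rep.f1,
            "precision": rep.precision, "recall": rep.recall,
            "zrb": rep.zrb, "f1_zrb_ratio": rep.f1_zrb_ratio,
            "kernel": rep.kernel, "C": rep.C,
            "n_train": rep.n_train, "n_test": rep.n_test,
        })
    return pd.DataFrame(rows)


def plot_overlays(originals: list[MovementVector],
                  generated: list[MovementVector],
                  subject_id, path) -> Path:
    """Mean +/- SD band of original vs generated curves for one subject."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = {"original": [t.values for t in originals
                           if t.subject_id == subject_id],
              "generated": [t.values for t in generated
                            if t.subject_id == subject_id]}
    for name, curves in groups.items():
        if len(curves) < 2:
            raise ValueError(
                f"need at least 2 {name} curves for subject {subject_id}")
    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(256)
    for (name, curves), color in zip(groups.items(), ("C0", "C1")):
        arr = np.stack(curves)
        mean, sd = arr.mean(axis=0), arr.std(axis=0)
        ax.plot(x, mean, color=color, label=f"{name} (n={len(curves)})")
        ax.fill_between(x, mean - sd, mean + sd, color=color, alpha=0.3)
    ax.set_xlabel("time point")
    ax.set_ylabel("normalized signal")
    ax.set_title(f"subject {subject_id}: original vs generated")
    ax.legend()
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
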