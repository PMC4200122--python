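"""End-to-end orchestration: counts + proteins in, SST calls, enrichment,
families and co-option statistics out."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import enrich, families, io, phylo, quantify

logger = logging.getLogger("silkshift")


@dataclass
class PipelineConfig:
    counts: str
    proteins: str | None = None
    hits: str | None = None
    go_map: str | None = None
    slim_map: str | None = None
    trees_dir: str | None = None  # optional <family_id>.nwk gene trees
    out_dir: str = "silkshift_out"
    tail_strict: float = 0.005
    tail_extended: float = 0.025
    floor: float = 1.0
    min_identity: float = 0.5
    min_coverage: float = 0.5
    alpha: float = 0.05
    use_pwf: bool = True
    reps: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.counts is None:
            raise ValueError("config: counts path is required")
        for name in ("counts", "proteins", "hits", "go_map", "slim_map", "trees_dir"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ValueError(f"config: {name} path does not exist: {value}")
        if not 0 < self.tail_strict <= self.tail_extended < 1:
            raise ValueError("config: need 0 < tail_strict <= tail_extended < 1")
        if self.reps < 1:
            raise ValueError("config: reps must be >= 1")


@dataclass
class RunReport:
    seed: int
    version: str
    stage_counts: dict = field(default_factory=dict)
    sst_classes: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    n_enriched: int | None = None
    n_depleted: int | None = None
    family_summaries: list = field(default_factory=list)
    mean_observed_shifts: float | None = None
    mean_expected_shifts: float | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=float)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.time() - t0)
            return result

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run quantify → call-SSTs → enrichment → families → co-option.

    Stages needing absent inputs (hits, GO map, proteins, trees) are skipped;
    intermediate artifacts are written to ``config.out_dir`` as they are
    produced.  Identical config + seed gives an identical report.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    report = RunReport(seed=config.seed, version=_version())

    matrix = io.read_counts_tsv(config.counts)
    report.stage_counts["transcripts"] = int(len(matrix.counts))

    ecpm = _quantify(matrix)
    calls, thr_strict, thr_ext = _call(ecpm, config)
    io.write_calls_tsv(calls, out / "sst_calls.tsv")
    io.write_json(
        {
            "strict": thr_strict.__dict__,
            "extended": thr_ext.__dict__,
        },
        out / "thresholds.json",
    )
    class_counts = calls["class"].value_counts().to_dict()
    report.sst_classes = {k: int(v) for k, v in class_counts.items()}
    report.thresholds = {"strict": thr_strict.__dict__, "extended": thr_ext.__dict__}

    sst_ids = set(calls.index[calls["class"].isin(quantify.SST_CLASSES)])
    extended_ids = set(calls.index[calls["class"].isin(quantify.EXTENDED_SET)])

    if config.go_map is not None:
        term_sets = io.read_go_map(config.go_map)
        lengths = (
            matrix.lengths.to_dict() if matrix.lengths is not None else None
        )
        universe = [
            t
            for t in calls.index[calls["class"] != quantify.BELOW_FLOOR]
            if term_sets.get(t)
        ]
        results = _enrich(sst_ids, term_sets, universe, lengths, config)
        results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        sig = results[results["significant"]]
        report.n_enriched = int((sig["direction"] == "enriched").sum())
        report.n_depleted = int((sig["direction"] == "depleted").sum())

    if config.proteins is not None:
        proteins = io.read_fasta(config.proteins)
        labels = {
            t: (
                "SST"
                if t in sst_ids
                else "extended-SST"
                if t in extended_ids
                else str(calls.loc[t, "class"])
            )
            for t in proteins
            if t in calls.index
        }
        sst_prot = {t: s for t, s in proteins.items() if t in extended_ids}
        other_prot = {t: s for t, s in proteins.items() if t not in extended_ids}
        fams = _families(sst_prot, other_prot, labels, config)
        with open(out / "families.tsv", "w") as fh:
            fh.write("family_id\tmember_id\tlabel\n")
            for fam in fams:
                for member, label in sorted(fam.members.items()):
                    fh.write(f"{fam.family_id}\t{member}\t{label}\n")
        report.stage_counts["families"] = len(fams)

        eligible = [f for f in fams if families.tree_eligible(f)]
        report.stage_counts["eligible_families"] = len(eligible)
        rng = np.random.default_rng(seeds[3])
        rows = []
        for fam in eligible:
            members = sorted(fam.members)
            if config.trees_dir is not None and (
                Path(config.trees_dir) / f"{fam.family_id}.nwk"
            ).exists():
                tree = phylo.read_newick(
                    (Path(config.trees_dir) / f"{fam.family_id}.nwk").read_text()
                )
            else:
                if len(members) < 3:
                    continue
                tree = phylo.build_distance_tree(
                    {m: proteins[m] for m in members}
                )
            rooted = phylo.midpoint_root(tree)
            states = {
                m: (phylo.SILK if fam.members[m] in families.SST_LABELS else phylo.NON_SILK)
                for m in members
            }
            null = _cooption(rooted, states, config, rng)
            rows.append(
                {
                    "family_id": fam.family_id,
                    "n_tips": len(members),
                    "n_silk": sum(1 for s in states.values() if s == phylo.SILK),
                    "observed": null.observed,
                    "null_mean": null.mean,
                    "null_sd": null.sd,
                    "p_emp": null.p_empirical,
                    "reps": null.reps,
                    "degenerate": null.degenerate,
                }
            )
        if rows:
            import pandas as pd

            shifts = pd.DataFrame(rows)
            shifts.to_csv(out / "cooption.tsv", sep="\t", index=False)
            report.family_summaries = rows
            report.mean_observed_shifts = float(shifts["observed"].mean())
            report.mean_expected_shifts = float(shifts["null_mean"].mean())

    (out / "report.json").write_text(report.to_json() + "\n")
    return report


@_stage("quantify")
def _quantify(matrix):
    return quantify.compute_ecpm(matrix)


@_stage("call-ssts")
def _call(ecpm, config):
    return quantify.call_ssts(
        ecpm,
        tail_strict=config.tail_strict,
        tail_extended=config.tail_extended,
        floor=config.floor,
    )


@_stage("enrich")
def _enrich(sst_ids, term_sets, universe, lengths, config):
    return enrich.enrichment_report(
        sst_ids,
        term_sets,
        universe,
        lengths=lengths,
        alpha=config.alpha,
        use_pwf=config.use_pwf,
    )


@_stage("families")
def _families(sst_prot, other_prot, labels, config):
    clusters = families.cluster_ssts(
        sst_prot, min_identity=config.min_identity, min_coverage=config.min_coverage
    )
    return families.augment_families(
        clusters,
        sst_prot,
        other_prot,
        labels=labels,
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
    )


def _cooption(tree, states, config, rng):
    return phylo.cooption_test(tree, states, reps=config.reps, rng=rng)


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("silkshift")
    except Exception:
        return "unknown"
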