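"""Configuration-driven pipeline orchestration.

Stages run in a fixed order — simulate/load, qc, label, split, select,
train, evaluate — each reading the artifacts of the previous stages from the
run directory and writing its own, so that running the stages one at a time
(e.g. through the command-line interface) is byte-identical to a monolithic
run.  All randomness is derived from a single global seed expanded into
per-stage seeds; the run report lists every seed used.
"""

from __future__ import annotations

import dataclasses
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, io, labels, qc, selection, split
from .forest import RFParams, expand_rf_grid, grid_search, impute_mode, train_multiview
from .simulate import CLINICAL_FEATURES, SimulationSpec, simulate_cohort

log = logging.getLogger("fingopred")

STAGE_ORDER = ("simulate", "qc", "label", "split", "select", "train", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = STAGE_ORDER.index(stage)
    return int(
        np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % (2**31)
    )


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of simulation/input paths is set."""

    simulation: SimulationSpec | None = None
    genotype_prefix: str | None = None
    clinical_path: str | None = None
    followup_path: str | None = None
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    fractions: tuple = split.DEFAULT_FRACTIONS
    #: (k, f_min) grid for the genetic signature search
    genetic_selection_grid: tuple = ((50, 0.1), (100, 0.2))
    #: (k, f_min) grid for the clinical signature search
    clinical_selection_grid: tuple = ((8, 0.5), (2, 0.05))
    selection_folds: int = 10
    selection_repeats: int = 20
    #: which set feeds the stability-selection CV ("Vset" or "TRset")
    selection_set: str = "Vset"
    genetic_rf_grid: dict = field(
        default_factory=lambda: {"ntree": (20, 50), "maxn": (10, 30), "nodesize": (2, 10)}
    )
    clinical_rf_grid: dict = field(
        default_factory=lambda: {
            "ntree": (20, 100),
            "maxn": (30, 100),
            "nodesize": (2,),
            "mtry": (3, None),
        }
    )
    #: the combined model keeps each view's full tree count (an allocation of
    #: 0.5 with 200 trees fuses two 100-tree single-view forests)
    multiview_params: dict = field(
        default_factory=lambda: {"ntree": 200, "maxn": 30, "nodesize": 2}
    )
    view_allocation: float = 0.5
    threshold: float = 0.5
    #: also simulate a cohort with outcome independent of the genetic signal
    #: and report the transfer AUROC of the frozen genetic model
    simulate_transfer: bool = False
    transfer_n: int = 300
    seed: int = 0

    def validate(self) -> None:
        has_paths = any(
            x is not None
            for x in (self.genotype_prefix, self.clinical_path, self.followup_path)
        )
        if self.simulation is None and not has_paths:
            raise ValueError("config needs a SimulationSpec or input paths")
        if self.simulation is not None and has_paths:
            raise ValueError("config must set either simulation or paths, not both")
        if has_paths and not all(
            x is not None
            for x in (self.genotype_prefix, self.clinical_path, self.followup_path)
        ):
            raise ValueError("genotype, clinical and follow-up paths are all required")
        fr = tuple(self.fractions)
        if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1) > 1e-9:
            raise ValueError("fractions must be 3 non-negative values summing to 1")
        if fr[2] == 0:
            raise ValueError("TEset fraction must be > 0 (evaluation impossible)")
        if self.selection_set not in ("Vset", "TRset"):
            raise ValueError("selection_set must be 'Vset' or 'TRset'")
        self.qc_thresholds.validate()

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        d["qc_thresholds"] = dataclasses.asdict(self.qc_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            for key in ("n_samples_per_cohort", "maf_range"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            if "eda_component_probs" in sim:
                sim["eda_component_probs"] = tuple(sim["eda_component_probs"])
            if isinstance(sim.get("causal_effect_sizes"), list):
                sim["causal_effect_sizes"] = tuple(sim["causal_effect_sizes"])
            d["simulation"] = SimulationSpec(**sim)
        if isinstance(d.get("qc_thresholds"), dict):
            d["qc_thresholds"] = qc.QCThresholds(**d["qc_thresholds"])
        for key in ("fractions", "genetic_selection_grid", "clinical_selection_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(tuple(x) if isinstance(x, list) else x for x in d[key])
        for key in ("genetic_rf_grid", "clinical_rf_grid"):
            if isinstance(d.get(key), dict):
                d[key] = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d[key].items()
                }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.read_yaml(path))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs missing artifact {path}; run the earlier stages"
        )
    return path


# ---------------------------------------------------------------------------
# stages


def run_stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    if config.simulation is None:
        log.info("simulate: external inputs configured, nothing to generate")
        return
    spec = dataclasses.replace(config.simulation)
    genotypes, clinical, followups = simulate_cohort(spec)
    io.write_genotypes(genotypes, outdir / "genotypes")
    io.write_clinical(clinical, outdir / "clinical.csv")
    io.write_followups(followups.frame, outdir / "followup.csv")
    truth = pd.DataFrame(
        {
            "patient_id": followups.latent_status.index,
            "latent_status": followups.latent_status.to_numpy(),
            "eda_probability": np.round(followups.eda_probability.to_numpy(), 6),
        }
    )
    truth.to_csv(outdir / "truth.csv", index=False)
    io.write_json(
        {"causal_snp_ids": followups.causal_snp_ids}, outdir / "truth_causal.json"
    )
    log.info(
        "simulate: %d samples x %d SNPs", genotypes.n_samples, genotypes.n_snps
    )

    if config.simulate_transfer:
        # same panel structure, causal effects zeroed: outcome independent of
        # the genetic signature (emulates patients on a different drug)
        tspec = dataclasses.replace(
            spec,
            n_samples_per_cohort=(config.transfer_n, 1),
            causal_effect_sizes=0.0,
            clinical_missing_rate=0.0,
            seed=spec.seed + 1,
        )
        tg, tc, tf = simulate_cohort(tspec)
        io.write_genotypes(tg, outdir / "transfer_genotypes")
        io.write_clinical(tc, outdir / "transfer_clinical.csv")
        io.write_followups(tf.frame, outdir / "transfer_followup.csv")


def _input_paths(config: PipelineConfig, outdir: Path) -> tuple[Path, Path, Path]:
    if config.simulation is not None:
        return (
            outdir / "genotypes",
            outdir / "clinical.csv",
            outdir / "followup.csv",
        )
    return (
        Path(config.genotype_prefix),
        Path(config.clinical_path),
        Path(config.followup_path),
    )


def run_stage_qc(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    gpfx, _, _ = _input_paths(config, outdir)
    _require(Path(str(gpfx) + io.DOSAGE_SUFFIX), "qc")
    genotypes = io.read_genotypes(gpfx)
    report = qc.run_qc(genotypes, config.qc_thresholds)
    qcdir = outdir / "qc"
    qcdir.mkdir(parents=True, exist_ok=True)
    report.removed_snps.to_csv(qcdir / "removed_snps.tsv", sep="\t", index=False)
    report.removed_samples.to_csv(
        qcdir / "removed_samples.tsv", sep="\t", index=False
    )
    pd.Series(report.pruned_snps, name="id").to_csv(
        qcdir / "pruned_snps.tsv", sep="\t", index=False
    )
    io.write_json(report.summary, qcdir / "summary.json")
    io.write_genotypes(report.retained, qcdir / "genotypes_qc")
    log.info("qc: %s", report.summary)


def run_stage_label(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    _, _, fpath = _input_paths(config, outdir)
    followups = io.read_followups(_require(Path(fpath), "label"))
    gm = io.read_genotypes(_require(Path(outdir / "qc" / "genotypes_qc.fam"), "label").parent / "genotypes_qc")
    post_qc_ids = set(gm.samples["id"])
    followups = followups[followups["patient_id"].isin(post_qc_ids)]
    retained = labels.apply_exclusions(followups)
    excluded = sorted(set(followups["patient_id"]) - set(retained["patient_id"]))
    lab = labels.classify_followups(retained)
    cohorts = gm.samples.set_index("id")["cohort"]
    accounting = labels.accounting_from_labels(lab, cohorts)
    accounting["ntz_excluded"] = len(excluded)
    lab.to_csv(outdir / "labels.csv", index=False)
    pd.Series(excluded, name="patient_id").to_csv(outdir / "excluded.csv", index=False)
    io.write_json(accounting, outdir / "accounting.json")
    log.info("label: %s", accounting)


def run_stage_split(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    lab = pd.read_csv(_require(outdir / "labels.csv", "split"), dtype={"patient_id": str})
    lab = lab[lab["status"] != labels.Status.UNCLASSIFIABLE.value]
    gm_samples = pd.read_csv(
        _require(outdir / "qc" / "genotypes_qc.fam", "split"), sep="\t",
        dtype={"id": str},
    )
    cohorts = gm_samples.set_index("id")["cohort"]
    assignment = split.stratified_split(
        labels=lab.set_index("patient_id")["status"],
        cohorts=cohorts,
        fractions=config.fractions,
        seed=stage_seed(config.seed, "split"),
    )
    frame = assignment.frame()
    frame["stratum"] = [f"{c}|{s}" for c, s in frame["stratum"]]
    frame.to_csv(outdir / "split.csv", index=False)
    log.info("split: sizes %s", assignment.sizes)


def _load_modelling_data(config: PipelineConfig, outdir: Path, stage: str):
    gm = io.read_genotypes(
        _require(outdir / "qc" / "genotypes_qc.fam", stage).parent / "genotypes_qc"
    )
    _, cpath, _ = _input_paths(config, outdir)
    clinical = io.read_clinical(cpath)
    lab = pd.read_csv(_require(outdir / "labels.csv", stage), dtype={"patient_id": str})
    sp = pd.read_csv(_require(outdir / "split.csv", stage), dtype={"patient_id": str})
    y = lab.set_index("patient_id")["status"]
    sets = sp.set_index("patient_id")["set"]
    X_gen = impute_mode(gm.dosage_frame().loc[sets.index])
    X_clin = (
        clinical.set_index("patient_id")[CLINICAL_FEATURES]
        .astype(float)
        .loc[sets.index]
    )
    y = (y.loc[sets.index] == evaluate.POSITIVE_STATUS).astype(int)
    return X_gen, X_clin, y, sets


def run_stage_select(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    X_gen, X_clin, y, sets = _load_modelling_data(config, outdir, "select")
    sel_ids = sets.index[sets == config.selection_set]
    seldir = outdir / "selection"
    seldir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, "select")
    for view, X, grid in (
        ("genetic", X_gen, config.genetic_selection_grid),
        ("clinical", X_clin, config.clinical_selection_grid),
    ):
        for k, f_min in grid:
            params = selection.SelectionParams(
                k=int(k),
                f_min=float(f_min),
                n_folds=config.selection_folds,
                n_repeats=config.selection_repeats,
                seed=seed,
            )
            result = selection.stability_select(X.loc[sel_ids], y.loc[sel_ids], params)
            tag = f"{view}_k{k}_f{f_min}"
            table = pd.DataFrame(
                {
                    "feature": result.frequencies.index,
                    "frequency": np.round(result.frequencies.to_numpy(), 6),
                    "mean_abs_corr": np.round(result.mean_abs_corr.to_numpy(), 6),
                }
            )
            table.to_csv(seldir / f"frequencies_{tag}.tsv", sep="\t", index=False)
            with open(seldir / f"signature_{tag}.txt", "w") as fh:
                fh.write("\n".join(map(str, result.signature)) + "\n")
            log.info("select: %s -> %d features", tag, len(result.signature))


def _read_signatures(config: PipelineConfig, outdir: Path, view: str, stage: str):
    grid = (
        config.genetic_selection_grid
        if view == "genetic"
        else config.clinical_selection_grid
    )
    out = {}
    for k, f_min in grid:
        tag = f"{view}_k{k}_f{f_min}"
        path = _require(outdir / "selection" / f"signature_{tag}.txt", stage)
        features = [l.strip() for l in path.read_text().splitlines() if l.strip()]
        params = selection.SelectionParams(
            k=int(k),
            f_min=float(f_min),
            n_folds=config.selection_folds,
            n_repeats=config.selection_repeats,
            seed=stage_seed(config.seed, "select"),
        )
        if not features:
            log.warning("select: signature %s is empty; skipped in training", tag)
            continue
        out[tag] = (params, features)
    return out


def run_stage_train(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    X_gen, X_clin, y, sets = _load_modelling_data(config, outdir, "train")
    tr_ids = sets.index[sets == "TRset"]
    v_ids = sets.index[sets == "Vset"]
    seed = stage_seed(config.seed, "train")
    modeldir = outdir / "models"
    modeldir.mkdir(parents=True, exist_ok=True)

    best = {}
    for view, X, grid_cfg in (
        ("genetic", X_gen, config.genetic_rf_grid),
        ("clinical", X_clin, config.clinical_rf_grid),
    ):
        signatures = _read_signatures(config, outdir, view, "train")
        if not signatures:
            raise RuntimeError(
                f"no usable {view} signature; selection produced empty sets"
            )
        view_tag = {"genetic": 1, "clinical": 2}[view]
        rf_grid = expand_rf_grid(
            base_seed=np.random.SeedSequence([seed, view_tag]).generate_state(1)[0]
            % (2**31),
            **grid_cfg,
        )
        records = grid_search(
            signatures,
            X.loc[tr_ids],
            y.loc[tr_ids],
            X.loc[v_ids],
            y.loc[v_ids],
            rf_grid,
            view=view,
            threshold=config.threshold,
        )
        pd.DataFrame([r.row() for r in records]).to_csv(
            modeldir / f"selection_records_{view}.tsv", sep="\t", index=False
        )
        with open(modeldir / f"best_{view}.pkl", "wb") as fh:
            pickle.dump(records[0], fh)
        best[view] = records[0]
        log.info(
            "train: best %s model %s (V AUROC %.3f, %d features)",
            view,
            records[0].model_id,
            records[0].metrics_v.auroc,
            len(records[0].signature),
        )

    mv_params = RFParams(
        seed=int(np.random.SeedSequence([seed, 999]).generate_state(1)[0] % (2**31)),
        **config.multiview_params,
    )
    mv = train_multiview(
        X_gen.loc[tr_ids, best["genetic"].signature],
        X_clin.loc[tr_ids, best["clinical"].signature],
        y.loc[tr_ids],
        mv_params,
        allocation=config.view_allocation,
    )
    with open(modeldir / "multiview.pkl", "wb") as fh:
        pickle.dump({"model": mv, "params": mv_params}, fh)


def run_stage_evaluate(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    X_gen, X_clin, y, sets = _load_modelling_data(config, outdir, "evaluate")
    te_ids = sets.index[sets == "TEset"]
    modeldir = outdir / "models"
    evdir = outdir / "evaluation"
    evdir.mkdir(parents=True, exist_ok=True)

    rows = []
    best = {}
    for view, X in (("genetic", X_gen), ("clinical", X_clin)):
        with open(_require(modeldir / f"best_{view}.pkl", "evaluate"), "rb") as fh:
            record = pickle.load(fh)
        best[view] = record
        scores = record.model.predict_proba1({view: X.loc[te_ids, record.signature]})
        record.metrics_te = evaluate.evaluate_scores(
            scores, y.loc[te_ids], "TEset", config.threshold
        )
        row = record.row()
        row["view"] = view
        rows.append(row)

    with open(_require(modeldir / "multiview.pkl", "evaluate"), "rb") as fh:
        mv = pickle.load(fh)["model"]

    def mv_scores(ids):
        return mv.predict_proba1(
            {
                "genetic": X_gen.loc[ids, best["genetic"].signature],
                "clinical": X_clin.loc[ids, best["clinical"].signature],
            }
        )

    tr_ids = sets.index[sets == "TRset"]
    mv_row = {"model": "multiview", "view": "multiview"}
    for tag, ids in (("tr", tr_ids), ("te", te_ids)):
        rep = evaluate.evaluate_scores(
            mv_scores(ids), y.loc[ids], tag.upper() + "set", config.threshold
        )
        mv_row.update(
            {
                f"{tag}_auroc": round(rep.auroc, 4),
                f"{tag}_auprc": round(rep.auprc, 4),
                f"{tag}_f": round(rep.f_score, 4),
                f"{tag}_acc": round(rep.accuracy, 4),
            }
        )
    rows.append(mv_row)
    pd.DataFrame(rows).to_csv(evdir / "metrics.tsv", sep="\t", index=False)

    # tertile stratification of the combined model's TE predictions
    te_scores = pd.Series(mv_scores(te_ids), index=te_ids)
    groups = evaluate.tertile_stratify(te_scores)
    _, _, fpath = _input_paths(config, outdir)
    followups = io.read_followups(fpath)
    lab = pd.read_csv(outdir / "labels.csv", dtype={"patient_id": str})
    comparison = evaluate.compare_groups(
        groups.prnr_ids, groups.prr_ids, followups, lab
    )
    io.write_json(comparison.as_dict(), evdir / "tertiles.json")

    if config.simulate_transfer and config.simulation is not None:
        tg = io.read_genotypes(outdir / "transfer_genotypes")
        tf = io.read_followups(outdir / "transfer_followup.csv")
        tlab = labels.classify_followups(labels.apply_exclusions(tf))
        tlab = tlab[tlab["status"] != labels.Status.UNCLASSIFIABLE.value]
        rep = evaluate.transfer_evaluate(
            best["genetic"].model,
            tg,
            tlab.set_index("patient_id")["status"],
            threshold=config.threshold,
        )
        io.write_json(rep.as_dict(), evdir / "transfer.json")
    log.info("evaluate: wrote %s", evdir / "metrics.tsv")


STAGES = {
    "simulate": run_stage_simulate,
    "qc": run_stage_qc,
    "label": run_stage_label,
    "split": run_stage_split,
    "select": run_stage_select,
    "train": run_stage_train,
    "evaluate": run_stage_evaluate,
}


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage in order; artifacts land in ``outdir``.

    The effective config (with all seeds) is echoed to ``config_used.yaml``.
    A stage failure aborts the run, leaving earlier artifacts plus a
    ``FAILED`` marker naming the stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    echo = config.to_dict()
    echo["stage_seeds"] = {s: stage_seed(config.seed, s) for s in STAGE_ORDER}
    io.write_yaml(echo, outdir / "config_used.yaml")
    for name in STAGE_ORDER:
        try:
            STAGES[name](config, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise RuntimeError(f"pipeline failed at stage {name!r}: {exc}") from exc
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return outdir
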