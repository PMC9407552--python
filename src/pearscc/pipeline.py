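"""End-to-end orchestration: simulate/load -> trim -> average replicates ->
preprocessing comparison -> SPXY split -> wavelength selection -> PSO-SVR.

Every stage's artifact can be persisted (CSV/JSON) together with a manifest
of SHA-256 content hashes, so a rerun with the same configuration and seed
reproduces identical files.  All stage seeds derive from one master seed via
``numpy.random.SeedSequence`` spawning, documented in ``derive_seeds``.

The preprocessing comparison needs a calibration/validation split while the
final split is defined on the preprocessed spectra; the pipeline therefore
computes a provisional SPXY split on the raw (trimmed, replicate-averaged)
spectra for the comparison stage only, then the definitive SPXY split on
the winning preprocessed spectra.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import preprocess as pp
from .datasets import (ReferenceSet, SpectraSet, average_replicates,
                       read_reference, read_spectra, replicate_groups,
                       summarize_reference, trim_to_effective_range,
                       write_reference, write_spectra)
from .selection import (McuveConfig, SpaConfig, WavelengthSelection,
                        mcuve_select, mcuve_stability, spa_select)
from .simulate import SyntheticConfig, generate
from .split import DatasetSplit, spxy_split, validate_split
from .svr import (FinalMetrics, PsoConfig, PSOSVR, evaluate_final)

log = logging.getLogger("pearscc")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration.  Exactly one of ``synthetic`` or
    (``spectra_csv``, ``reference_csv``) must be provided."""

    synthetic: SyntheticConfig | None = None
    spectra_csv: str | None = None
    reference_csv: str | None = None
    effective_range: tuple[float, float] = (498.0, 1020.0)
    preprocessing: str | None = None   # e.g. "snv"; None -> run comparison
    split_ratio: tuple[int, int] = (3, 1)
    selection_method: str = "mcuve"    # "mcuve" or "spa"
    spa: SpaConfig = field(default_factory=SpaConfig)
    mcuve: McuveConfig = field(default_factory=McuveConfig)
    pso: PsoConfig = field(default_factory=PsoConfig)
    max_factors: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.spectra_csv is not None and self.reference_csv is not None
        if (self.synthetic is None) == (not has_files):
            raise ValueError("provide exactly one of: synthetic config, "
                             "or spectra_csv + reference_csv")
        if self.selection_method not in ("mcuve", "spa"):
            raise ValueError("selection_method must be 'mcuve' or 'spa'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            syn = dict(d["synthetic"])
            for key in ("grid", "scc_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            for key in ("band_centers", "band_amplitudes"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "informative_slopes" in syn:
                syn["informative_slopes"] = {
                    float(k): float(v)
                    for k, v in syn["informative_slopes"].items()}
            d["synthetic"] = SyntheticConfig(**syn)
        for key, typ in (("spa", SpaConfig), ("mcuve", McuveConfig),
                         ("pso", PsoConfig)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for tk in ("inertia", "c_bounds", "g_bounds"):
                    if tk in sub:
                        sub[tk] = tuple(sub[tk])
                d[key] = typ(**sub)
        for key in ("effective_range", "split_ratio"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        return cls.from_dict(data)


def derive_seeds(master: int, n: int = 4) -> list[int]:
    """Stage seeds (data, mcuve, pso, reserve) derived from the master seed
    by SeedSequence spawning; each is a 31-bit integer."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


@dataclass
class EvaluationReport:
    """Provenance plus metrics of one pipeline run."""

    config: dict
    seeds: dict
    set_statistics: dict
    split: dict
    preprocessing: dict
    selection: dict
    svr: dict
    metrics: dict
    warnings: list
    no_skill: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))


def _config_to_jsonable(cfg: PipelineConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [conv(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, np.generic):
            return obj.item()
        return obj
    return conv(cfg)


# artifact persistence -------------------------------------------------------

class _ArtifactStore:
    def __init__(self, outdir: Path | None):
        self.outdir = outdir
        self.manifest: dict[str, str] = {}
        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)

    def _register(self, name: str) -> None:
        path = self.outdir / name
        self.manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def spectra(self, name: str, s: SpectraSet) -> None:
        if self.outdir is None:
            return
        write_spectra(s, self.outdir / name)
        self._register(name)

    def reference(self, name: str, r: ReferenceSet) -> None:
        if self.outdir is None:
            return
        write_reference(r, self.outdir / name)
        self._register(name)

    def json(self, name: str, obj) -> None:
        if self.outdir is None:
            return
        (self.outdir / name).write_text(
            json.dumps(obj, indent=2, sort_keys=True), encoding="utf-8")
        self._register(name)

    def finish(self) -> None:
        if self.outdir is None:
            return
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True),
            encoding="utf-8")


NO_SKILL_R = 0.35  # validation |R| below this flags a no-skill outcome


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None
                 ) -> EvaluationReport:
    """Execute the full pipeline; optionally persist stage artifacts plus a
    manifest of their SHA-256 hashes under ``outdir``."""
    store = _ArtifactStore(Path(outdir) if outdir is not None else None)
    seeds = derive_seeds(cfg.seed)
    seed_map = {"master": cfg.seed, "data": seeds[0], "mcuve": seeds[1],
                "pso": seeds[2]}
    report_warnings: list[str] = []
    stage = "load"
    try:
        t0 = time.perf_counter()
        if cfg.synthetic is not None:
            spectra, reference, _truth = generate(cfg.synthetic,
                                                  seed=seeds[0])
            store.spectra("spectra_raw.csv", spectra)
            store.reference("reference.csv", reference)
        else:
            spectra = read_spectra(cfg.spectra_csv)
            reference = read_reference(cfg.reference_csv)
        log.info("stage load: %d rows x %d channels (%.2fs)",
                 spectra.n_samples, spectra.n_channels,
                 time.perf_counter() - t0)

        stage = "trim"
        spectra = trim_to_effective_range(spectra, *cfg.effective_range)
        store.spectra("spectra_trimmed.csv", spectra)

        stage = "average_replicates"
        spectra = average_replicates(spectra,
                                     replicate_groups(spectra.sample_ids))
        store.spectra("spectra_averaged.csv", spectra)
        y_all = reference.aligned_to(spectra)

        stage = "preprocess"
        if cfg.preprocessing is not None:
            spec = pp.PreprocessSpec.parse(cfg.preprocessing)
            comparison_rows = None
        else:
            provisional = spxy_split(spectra.reflectance, y_all,
                                     cfg.split_ratio)
            comparison = pp.compare_preprocessing(
                spectra, reference, provisional, max_factors=cfg.max_factors)
            spec = comparison.winner.spec
            comparison_rows = comparison.to_dicts()
        preprocessed = pp.apply(spec, spectra)
        store.spectra("spectra_preprocessed.csv", preprocessed)
        if comparison_rows is not None:
            store.json("preprocessing_comparison.json", comparison_rows)

        stage = "split"
        split = spxy_split(preprocessed, reference, cfg.split_ratio)
        split_report = validate_split(split, y_all)
        store.json("split.json", {**split.to_dict(),
                                  "report": split_report.to_dict()})
        X = preprocessed.reflectance
        cal, val = split.calibration_idx, split.validation_idx
        Xc, yc = X[cal], y_all[cal]
        Xv, yv = X[val], y_all[val]

        stage = "selection"
        if cfg.selection_method == "spa":
            selection = spa_select(Xc, yc, Xv, yv, cfg.spa)
        else:
            mc = dataclasses.replace(cfg.mcuve, seed=seeds[1])
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                stability = mcuve_stability(Xc, yc, mc)
                selection = mcuve_select(stability, Xc, yc, Xv, yv, mc)
            report_warnings += [str(w.message) for w in caught]
        sel_idx = selection.selected
        store.json("selection.json", {
            "method": selection.method,
            "selected_indices": sel_idx.tolist(),
            "selected_wavelengths_nm": preprocessed.wavelengths[
                np.sort(sel_idx)].tolist(),
            "trajectory": selection.trajectory.tolist()})

        stage = "svr"
        pso = dataclasses.replace(cfg.pso, seed=seeds[2])
        model = PSOSVR(config=pso).fit(Xc[:, sel_idx], yc)
        store.json("model.json", {
            "c": model.best_params_.c, "g": model.best_params_.g,
            "epsilon": model.best_params_.epsilon,
            "fitness": model.best_fitness_,
            "fitness_trajectory": model.trajectory_.tolist()})

        stage = "evaluate"
        metrics = evaluate_final(model, split, X[:, sel_idx], y_all)
        no_skill = abs(metrics.r_v) < NO_SKILL_R
        report = EvaluationReport(
            config=_config_to_jsonable(cfg),
            seeds=seed_map,
            set_statistics={
                "calibration": summarize_reference(yc).to_dict(),
                "validation": summarize_reference(yv).to_dict()},
            split={"n_calibration": int(cal.size),
                   "n_validation": int(val.size),
                   "covers": split_report.covers,
                   "anova_p": split_report.anova_p},
            preprocessing={"chosen": spec.name,
                           "comparison": comparison_rows},
            selection={"method": selection.method,
                       "n_selected": int(sel_idx.size),
                       "selected_wavelengths_nm": preprocessed.wavelengths[
                           np.sort(sel_idx)].tolist(),
                       "min_rmsev": float(selection.trajectory.min())},
            svr={"c": model.best_params_.c, "g": model.best_params_.g,
                 "epsilon": model.best_params_.epsilon,
                 "fitness": model.best_fitness_},
            metrics=metrics.to_dict(),
            warnings=report_warnings,
            no_skill=bool(no_skill))
        store.json("report.json", report.to_dict())
        store.finish()
        return report
    except Exception as exc:
        store.finish()  # persist the partial manifest for debugging
        raise PipelineStageError(stage, exc) from exc


def render_report(report: EvaluationReport, outdir: str | Path,
                  formats: tuple[str, ...] = ("json",),
                  plots: bool = False) -> list[Path]:
    """Write the report as JSON and optionally CSV tables and plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fmt in formats:
        if fmt == "json":
            path = outdir / "report.json"
            path.write_text(report.to_json(), encoding="utf-8")
            written.append(path)
        elif fmt == "csv":
            import csv as _csv
            path = outdir / "preprocessing_comparison.csv"
            rows = report.preprocessing.get("comparison") or [
                {"preprocessing": report.preprocessing["chosen"]}]
            with path.open("w", newline="", encoding="utf-8") as fh:
                writer = _csv.DictWriter(fh, fieldnames=list(rows[0]))
                writer.writeheader()
                writer.writerows(rows)
            written.append(path)
        else:
            raise ValueError(f"unknown report format {fmt!r}")
    if plots:
        written += _render_plots(report, outdir)
    return written


def _render_plots(report: EvaluationReport, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    wl = report.selection.get("selected_wavelengths_nm")
    if wl:
        fig, ax = plt.subplots(figsize=(7, 2.5))
        ax.stem(wl, np.ones(len(wl)), basefmt=" ")
        ax.set_xlabel("wavelength (nm)")
        ax.set_yticks([])
        ax.set_title(f"selected wavelengths ({report.selection['method']})")
        path = outdir / "selected_wavelengths.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
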