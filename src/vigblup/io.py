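"""Readers, writers, run configuration and the end-to-end pipeline.

All tables are plain UTF-8 CSV with headers. Genotypes are accepted either
as a plain matrix CSV (rows = individuals, columns = markers, values
0/1/2/NA) or as VCF (GT mapped to ALT dosage; multiallelic records skipped
with a logged count). GRMs are square CSVs with the ids as header and
index. Run configuration is YAML with a versioned schema in which unknown
keys are errors — silent typos are the main operational risk.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FormatError, ParameterError, SchemaError
from .grm import GenotypeMatrix, RelationshipMatrix

logger = logging.getLogger("vigblup.io")

#: float format used by every writer so reruns are byte-identical
FLOAT_FORMAT = "%.10g"


def configure_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("vigblup")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)


def stage_logger(stage: str, seed: int | None) -> logging.LoggerAdapter:
    """Logger whose every line carries the stage and seed."""
    base = logging.getLogger(f"vigblup.{stage}")
    prefix = f"stage={stage} seed={seed}"

    class _Adapter(logging.LoggerAdapter):
        def process(self, msg, kwargs):
            return f"{prefix} {msg}", kwargs

    return _Adapter(base, {})


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path, fmt: str = "auto", panel: str = "unlabeled") -> GenotypeMatrix:
    """Read a genotype matrix from CSV or VCF.

    CSV: first column individual ids, remaining columns markers, entries
    0/1/2 or NA. VCF: GT fields mapped to ALT-allele dosage (./. → missing);
    multiallelic records are skipped and counted in a log line.

    Raises
    ------
    FormatError
        On an empty or unparseable file.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz") else "csv"
    if fmt == "csv":
        try:
            frame = pd.read_csv(path, index_col=0)
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as genotype CSV: {exc}") from exc
        if frame.empty:
            raise FormatError(f"{path} contains no genotype calls")
        return GenotypeMatrix.from_frame(frame, panel=panel)
    if fmt == "vcf":
        return _read_vcf(path, panel)
    raise ParameterError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path, panel: str) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("VCF support requires cyvcf2") from exc
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:
        raise FormatError(f"cannot open {path} as VCF: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")
    columns, marker_ids, n_multi = [], [], 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(variant.gt_types, dtype=float)  # 0/1/2, 3=missing
        gt[gt == 3] = np.nan
        columns.append(gt)
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if n_multi:
        logger.warning("skipped %d multiallelic record(s) in %s", n_multi, path)
    if not columns:
        raise FormatError(f"{path}: no biallelic records found")
    calls = np.column_stack(columns)
    return GenotypeMatrix(individual_ids=samples, marker_ids=marker_ids, calls=calls, panel=panel)


def write_genotypes_csv(g: GenotypeMatrix, path: str | Path) -> None:
    g.to_frame().to_csv(path, na_rep="NA", float_format="%g")


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Minimal single-chromosome VCF with GT-only genotype fields."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individual_ids) + "\n")
        for j, marker in enumerate(g.marker_ids):
            fields = ["1", str(j + 1), marker, "A", "T", ".", "PASS", ".", "GT"]
            for i in range(g.n_individuals):
                call = g.calls[i, j]
                fields.append("./." if np.isnan(call) else code[call])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# phenotypes, pedigree, GRM, weather

WIDE_REQUIRED = ("plot_id", "hybrid_id", "replicate", "site_year")
LONG_EXTRA = ("time_label", "gdd", "value")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy plot table (wide traits or long VI format).

    Wide: ``plot_id, hybrid_id, replicate, site_year`` plus trait columns;
    ``plot_id`` must be unique. Long: the same keys plus
    ``time_label, gdd, value``; ``(plot_id, time_label)`` must be unique.

    Raises
    ------
    SchemaError
        Naming the first missing column, or on duplicate rows.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
    missing = [c for c in WIDE_REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"phenotype table missing column {missing[0]!r}")
    is_long = all(c in frame.columns for c in LONG_EXTRA)
    if is_long:
        if frame.duplicated(subset=["plot_id", "time_label"]).any():
            raise SchemaError("duplicate (plot_id, time_label) rows")
    else:
        traits = [c for c in frame.columns if c not in WIDE_REQUIRED]
        if not traits:
            raise SchemaError("wide phenotype table has no trait columns")
        if frame.duplicated(subset=["plot_id"]).any():
            raise SchemaError("duplicate plot_id rows")
    return frame


def read_pedigree(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("hybrid_id", "mother_id", "father_id") if c not in frame.columns]
    if missing:
        raise SchemaError(f"pedigree missing column {missing[0]!r}")
    return frame.astype(str)


def read_weather(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("date", "tmin", "tmax") if c not in frame.columns]
    if missing:
        raise SchemaError(f"weather table missing column {missing[0]!r}")
    return frame


def write_grm(grm: RelationshipMatrix, path: str | Path) -> None:
    grm.to_frame().to_csv(path, float_format="%.12g")


def read_grm(path: str | Path) -> RelationshipMatrix:
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index.astype(str)) != [str(c) for c in frame.columns]:
        raise SchemaError(f"{path}: GRM header and index ids differ")
    frame.index = frame.index.astype(str)
    frame.columns = [str(c) for c in frame.columns]
    return RelationshipMatrix.from_frame(frame)


def identity_grm(ids: list[str]) -> RelationshipMatrix:
    """Identity relationship (no marker information); the --no-grm toggle."""
    return RelationshipMatrix(ids=list(ids), values=np.eye(len(ids)))


# ---------------------------------------------------------------------------
# run configuration

CONFIG_VERSION = 1

_ALLOWED_KEYS: dict[str, set[str] | None] = {
    "version": None,
    "seed": None,
    "output_dir": None,
    "simulate": {
        "n_maternal", "n_paternal", "n_markers", "n_hybrids", "n_reps",
        "flight_gdds", "knot_gdds", "eos_h2", "r_g_eos", "eos_vi_flight", "site_year",
    },
    "paths": {
        "genotypes_maternal", "genotypes_paternal", "pedigree",
        "phenotypes", "vi_long", "weather", "grm",
    },
    "qc": {"max_missing", "min_maf", "max_het"},
    "st": {"trait", "tol", "max_iter"},
    "mt": {"trait", "secondary_trait", "time_label", "tol", "max_iter"},
    "rr": {"knots", "tol", "max_iter"},
    "cv": {"trait", "secondary_trait", "time_label", "folds", "seed", "use_grm"},
}


class RunConfig:
    """Validated YAML run configuration (versioned schema, unknown keys fatal)."""

    def __init__(self, raw: dict, base_dir: Path):
        if not isinstance(raw, dict):
            raise SchemaError("config must be a mapping")
        unknown = set(raw) - set(_ALLOWED_KEYS)
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        version = raw.get("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise SchemaError(f"unsupported config version {version}")
        for section, allowed in _ALLOWED_KEYS.items():
            block = raw.get(section)
            if allowed is not None and isinstance(block, dict):
                bad = set(block) - allowed
                if bad:
                    raise SchemaError(f"unknown key(s) in {section!r}: {sorted(bad)}")
        self.raw = raw
        self.seed = int(raw.get("seed", 0))
        self.output_dir = Path(raw.get("output_dir", "vigblup_out"))
        if not self.output_dir.is_absolute():
            self.output_dir = base_dir / self.output_dir
        self.paths = {}
        for key, value in (raw.get("paths") or {}).items():
            p = Path(value)
            if not p.is_absolute():
                p = base_dir / p
            if not p.exists():
                raise SchemaError(f"configured path does not exist: {key} = {p}")
            self.paths[key] = p
        # preflight: stages must have the inputs they will need before any compute
        if "simulate" not in raw:
            needs_vi = {"rr", "mt"} & set(raw)
            if needs_vi and "vi_long" not in self.paths:
                raise SchemaError(f"stage(s) {sorted(needs_vi)} require paths.vi_long (or a simulate block)")
            needs_eos = {"st", "mt", "cv"} & set(raw)
            if needs_eos and "phenotypes" not in self.paths:
                raise SchemaError(f"stage(s) {sorted(needs_eos)} require paths.phenotypes (or a simulate block)")

    def block(self, name: str) -> dict | None:
        return self.raw.get(name)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw or {}, base_dir=path.parent)


# ---------------------------------------------------------------------------
# pipeline


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages end to end and write a manifest.

    Stages run in order simulate/ingest → QC → GRM → model fits → CV; each
    stage logs with its seed and writes its outputs under the configured
    output directory. Any failure halts with the stage name; outputs written
    so far are left in place.
    """
    from . import cv as cv_mod
    from . import gblup, grm as grm_mod, random_regression as rr_mod, simulate as sim_mod

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "vigblup",
        "version": __version__,
        "seed": config.seed,
        "started_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
        "stages": [],
    }
    artifacts: dict = {}

    def run_stage(name, fn):
        log = stage_logger(name, config.seed)
        log.info("starting")
        try:
            outputs = fn(log) or []
        except Exception as exc:
            manifest["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
            _write_manifest(manifest, out)
            raise StageFailure(name, exc) from exc
        manifest["stages"].append({"stage": name, "status": "ok", "outputs": outputs})
        log.info("done")

    if config.block("simulate") is not None:
        def _simulate(log):
            kwargs = dict(config.block("simulate") or {})
            for tuple_key in ("flight_gdds", "knot_gdds"):
                if tuple_key in kwargs:
                    kwargs[tuple_key] = tuple(float(v) for v in kwargs[tuple_key])
            sim = sim_mod.simulate_dataset(sim_mod.SimulationConfig(seed=config.seed, **kwargs))
            artifacts.update(sim)
            write_genotypes_csv(sim["maternal"], out / "genotypes_maternal.csv")
            write_genotypes_csv(sim["paternal"], out / "genotypes_paternal.csv")
            sim["pedigree"].to_csv(out / "pedigree.csv", index=False)
            sim["layout"].to_csv(out / "layout.csv", index=False)
            sim["vi_long"].to_csv(out / "vi_long.csv", index=False, float_format=FLOAT_FORMAT)
            sim["eos"].to_csv(out / "phenotypes.csv", index=False, float_format=FLOAT_FORMAT)
            sim["weather"].to_csv(out / "weather.csv", index=False)
            write_grm(sim["grm_hybrid"], out / "grm_hybrid.csv")
            return [str(p.name) for p in out.glob("*.csv")]
        run_stage("simulate", _simulate)
    else:
        def _ingest(log):
            if "phenotypes" in config.paths:
                artifacts["eos"] = read_phenotypes(config.paths["phenotypes"])
            if "vi_long" in config.paths:
                artifacts["vi_long"] = read_phenotypes(config.paths["vi_long"])
            if "pedigree" in config.paths:
                artifacts["pedigree"] = read_pedigree(config.paths["pedigree"])
            if "grm" in config.paths:
                artifacts["grm_hybrid"] = read_grm(config.paths["grm"])
            elif {"genotypes_maternal", "genotypes_paternal", "pedigree"} <= set(config.paths):
                qc_kwargs = config.block("qc") or {}
                grms = {}
                for side in ("maternal", "paternal"):
                    g = read_genotypes(config.paths[f"genotypes_{side}"], panel=side)
                    g, report = grm_mod.qc_markers(g, **qc_kwargs)
                    log.info("%s QC: %s", side, report.summary())
                    grms[side] = grm_mod.vanraden_grm(grm_mod.impute_mode(g))
                artifacts["grm_hybrid"] = grm_mod.hybrid_grm(
                    grms["maternal"], grms["paternal"], artifacts["pedigree"]
                )
                write_grm(artifacts["grm_hybrid"], out / "grm_hybrid.csv")
            return []
        run_stage("ingest", _ingest)

    if config.block("st") is not None:
        def _st(log):
            block = dict(config.block("st"))
            trait = block.pop("trait")
            spec = gblup.build_st_spec(artifacts["eos"], trait, artifacts["grm_hybrid"])
            fit = gblup.fit_st_gblup(spec, **block)
            log.info("sigma_a2=%.6g sigma_e2=%.6g h2=%.4f converged=%s",
                     fit.sigma_a2, fit.sigma_e2, fit.h2, fit.converged)
            report = pd.DataFrame(
                {"parameter": ["sigma_a2", "sigma_e2", "h2", "loglik", "n_iter", "converged"],
                 "value": [fit.sigma_a2, fit.sigma_e2, fit.h2, fit.loglik, fit.n_iter, int(fit.converged)]}
            )
            report.to_csv(out / f"st_{trait}.csv", index=False, float_format=FLOAT_FORMAT)
            fit.a_hat.rename("genetic_value").rename_axis("hybrid_id").reset_index().to_csv(
                out / f"st_{trait}_blup.csv", index=False, float_format=FLOAT_FORMAT
            )
            artifacts[f"st_fit:{trait}"] = fit
            return [f"st_{trait}.csv", f"st_{trait}_blup.csv"]
        run_stage("fit-st", _st)

    if config.block("mt") is not None:
        def _mt(log):
            block = dict(config.block("mt"))
            trait = block.pop("trait")
            secondary = block.pop("secondary_trait")
            time_label = block.pop("time_label")
            vi = artifacts["vi_long"]
            vi_t = vi.loc[(vi["time_label"] == time_label)].copy()
            vi_t = vi_t.rename(columns={"value": secondary})
            spec1 = gblup.build_st_spec(artifacts["eos"], trait, artifacts["grm_hybrid"])
            spec2 = gblup.build_st_spec(vi_t, secondary, artifacts["grm_hybrid"])
            fit = gblup.fit_mt_gblup(spec1, spec2, **block)
            log.info("r_g=%.4f r_e=%.4f converged=%s", fit.r_g, fit.r_e, fit.converged)
            pd.DataFrame(
                {"parameter": ["sg11", "sg12", "sg22", "se11", "se12", "se22", "r_g", "r_e", "loglik"],
                 "value": [fit.Sigma_g[0, 0], fit.Sigma_g[0, 1], fit.Sigma_g[1, 1],
                           fit.Sigma_e[0, 0], fit.Sigma_e[0, 1], fit.Sigma_e[1, 1],
                           fit.r_g, fit.r_e, fit.loglik]}
            ).to_csv(out / f"mt_{trait}_{secondary}_{time_label}.csv", index=False,
                     float_format=FLOAT_FORMAT)
            return [f"mt_{trait}_{secondary}_{time_label}.csv"]
        run_stage("fit-mt", _mt)

    if config.block("rr") is not None:
        def _rr(log):
            block = dict(config.block("rr"))
            knot_idx = block.pop("knots", None)
            vi = artifacts["vi_long"]
            flights = np.sort(vi["gdd"].unique())
            knots = flights[knot_idx] if knot_idx is not None else np.asarray(
                artifacts["config"].knot_gdds if "config" in artifacts else flights[[0, len(flights) // 2, -1]]
            )
            design = rr_mod.build_rr_design(vi, knots, artifacts["grm_hybrid"])
            fit = rr_mod.fit_random_regression(design, artifacts["grm_hybrid"], **block)
            log.info("converged=%s loglik=%.4f", fit.converged, fit.loglik)
            pd.DataFrame(fit.Sigma_a).to_csv(out / "rr_sigma_a.csv", float_format=FLOAT_FORMAT)
            pd.DataFrame(fit.Sigma_pe).to_csv(out / "rr_sigma_pe.csv", float_format=FLOAT_FORMAT)
            fit.resid_vars.to_csv(out / "rr_resid_vars.csv", float_format=FLOAT_FORMAT)
            fit.a_hat.rename_axis("hybrid_id").to_csv(out / "rr_coefficients.csv",
                                                      float_format=FLOAT_FORMAT)
            grid = rr_mod.reconstruct_covariance_grid(fit.Sigma_a, fit.knot_gdds, flights)
            grid.to_csv(out / "rr_covariance_grid.csv", float_format=FLOAT_FORMAT)
            artifacts["rr_fit"] = fit
            return ["rr_sigma_a.csv", "rr_sigma_pe.csv", "rr_resid_vars.csv",
                    "rr_coefficients.csv", "rr_covariance_grid.csv"]
        run_stage("fit-rr", _rr)

    if config.block("cv") is not None:
        def _cv(log):
            block = dict(config.block("cv"))
            trait = block.pop("trait")
            secondary = block.pop("secondary_trait", None)
            time_label = block.pop("time_label", None)
            k = int(block.pop("folds", 5))
            cv_seed = int(block.pop("seed", config.seed))
            use_grm = bool(block.pop("use_grm", True))
            grm_used = artifacts["grm_hybrid"] if use_grm else identity_grm(artifacts["grm_hybrid"].ids)
            folds = cv_mod.make_folds(list(grm_used.ids), k=k, seed=cv_seed)
            folds.to_frame().to_csv(out / "cv_folds.csv", index=False)
            st_res = cv_mod.run_st_cv(artifacts["eos"], trait, folds, grm_used)
            rows = [{"model": st_res.model, "fold": i + 1, "accuracy": a}
                    for i, a in enumerate(st_res.fold_accuracies)]
            if secondary is not None:
                vi = artifacts["vi_long"]
                vi_t = vi.loc[vi["time_label"] == time_label]
                mt_res = cv_mod.run_mt_cv(artifacts["eos"], trait, vi_t, secondary, folds, grm_used)
                rows += [{"model": mt_res.model, "fold": i + 1, "accuracy": a}
                         for i, a in enumerate(mt_res.fold_accuracies)]
                log.info("mean accuracy ST=%.4f MT=%.4f", st_res.mean_accuracy, mt_res.mean_accuracy)
            pd.DataFrame(rows).to_csv(out / f"cv_{trait}.csv", index=False,
                                      float_format=FLOAT_FORMAT)
            return ["cv_folds.csv", f"cv_{trait}.csv"]
        run_stage("cv", _cv)

    manifest["finished_utc"] = dt.datetime.now(dt.timezone.utc).isoformat()
    _write_manifest(manifest, out)
    return {"manifest": manifest, "artifacts": artifacts}


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
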