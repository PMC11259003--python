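"""End-to-end pipeline: synth/load -> QC -> association -> OPLS-DA ->
enrichment -> network -> validation -> simulation, with a run manifest.

Every stage writes its artifacts under the output directory and the
manifest records the parameter echo, the master seed and a SHA-256 checksum
per written file, so a rerun with the same config is byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, discrim, enrich, network, preprocess, synthdata
from .cohort import CohortMatrix, read_cohort
from .resample import SmoteParams

log = logging.getLogger("adrenosig")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the analysis' stated settings."""

    # inputs: either file paths or a synthetic cohort
    matrix_path: str | None = None
    sample_meta_path: str | None = None
    metabolite_meta_path: str | None = None
    pathway_path: str | None = None
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    use_synthetic: bool = True

    cutoff: float = 350.0
    min_present: float = 0.70
    smote_k: int = 3
    smote_replications: int = 3
    n_resamples: int = 1000
    fdr_alpha: float = 0.05
    vip_cutoff: float = 1.5
    n_ortho: int = 1
    n_folds: int = 7
    n_perm: int = 1000
    correlation_threshold: float = 0.8
    similarity_threshold: float = 0.7
    run_validation: bool = True
    seed: int = 0
    outdir: str = "adrenosig_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        checks = [
            (0 < self.min_present <= 1, "min_present in (0,1]"),
            (self.cutoff > 0, "cutoff > 0"),
            (self.smote_k >= 1, "smote_k >= 1"),
            (self.smote_replications >= 0, "smote_replications >= 0"),
            (self.n_resamples >= 1, "n_resamples >= 1"),
            (0 < self.fdr_alpha < 1, "fdr_alpha in (0,1)"),
            (self.n_folds >= 2, "n_folds >= 2"),
            (0 < self.correlation_threshold <= 1, "correlation_threshold in (0,1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: requires {msg}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    written: list[Path] = []

    def record(stage: str, paths) -> None:
        files = list(paths.values()) if isinstance(paths, dict) else list(paths)
        manifest["stages"][stage] = {
            str(p.relative_to(outdir)): _sha256(p) for p in files
        }
        written.extend(files)
        log.info("stage %s wrote %d file(s)", stage, len(files))

    def stage_fail(stage: str, err: Exception) -> RuntimeError:
        return RuntimeError(f"pipeline stage {stage!r} failed: {err}")

    # -- stage 1: cohort ------------------------------------------------------
    truth = None
    try:
        if config.use_synthetic:
            synth_cfg = synthdata.SynthConfig(**{"seed": config.seed, **config.synth})
            cohort_s = synthdata.generate_cohort(synth_cfg)
            raw, truth = cohort_s.matrix, cohort_s.truth
            paths = raw.write(outdir, prefix="raw")
            tpath = outdir / "truth.tsv"
            truth.to_csv(tpath, sep="\t")
            paths["truth"] = tpath
        else:
            raw = read_cohort(
                config.matrix_path, config.sample_meta_path, config.metabolite_meta_path
            )
            paths = raw.write(outdir, prefix="raw")
    except Exception as e:  # noqa: BLE001
        raise stage_fail("cohort", e) from e
    record("cohort", paths)

    # -- stage 2: qc -----------------------------------------------------------
    try:
        processed, qc = preprocess.run_qc(raw, config.min_present, config.cutoff)
        qc.write(outdir)
        paths = processed.write(outdir, prefix="processed")
        paths["qc_report"] = outdir / "qc_report.json"
        paths["qc_per_met"] = outdir / "qc_per_metabolite.tsv"
    except Exception as e:  # noqa: BLE001
        raise stage_fail("qc", e) from e
    record("qc", paths)

    params = SmoteParams(config.smote_k, config.smote_replications, seed=config.seed)

    # -- stage 3: association --------------------------------------------------
    try:
        table = assoc.repeated_association(
            processed, params, n_resamples=config.n_resamples, fdr_alpha=config.fdr_alpha
        )
        apath = outdir / "association.tsv"
        table.to_csv(apath, sep="\t", index_label="metabolite_id")
    except Exception as e:  # noqa: BLE001
        raise stage_fail("assoc", e) from e
    record("assoc", [apath])
    hits = list(table.index[table["significant"].fillna(False)])

    # -- stage 4: discriminant analysis ----------------------------------------
    try:
        X = processed.abundances.to_numpy(dtype=float)
        y = processed.group_indicator()
        # the discriminant model is fitted on oversampled data, like the
        # association models; model-level validation uses the same resample
        from .resample import resample_stream

        res0 = next(iter(resample_stream(X, y, params, 1)))
        model = discrim.OPLSDA(n_ortho=config.n_ortho).fit(res0.X, res0.y)
        q2 = discrim.q2y(res0.X, res0.y, config.n_ortho, config.n_folds, seed=config.seed)
        p_perm, _, _ = discrim.permutation_test(
            res0.X, res0.y, n_perm=config.n_perm, n_ortho=config.n_ortho,
            n_folds=config.n_folds, seed=config.seed,
        )
        viptab = discrim.repeated_vip(
            processed, params, n_resamples=config.n_resamples,
            n_ortho=config.n_ortho, vip_cutoff=config.vip_cutoff,
        )
        vpath = outdir / "vip.tsv"
        viptab.to_csv(vpath, sep="\t", index_label="metabolite_id")
        spath = outdir / "oplsda_summary.json"
        spath.write_text(json.dumps({"r2y": model.r2y_, "q2y": q2, "p_perm": p_perm}, indent=2) + "\n")
    except Exception as e:  # noqa: BLE001
        raise stage_fail("discrim", e) from e
    record("discrim", [vpath, spath])

    # -- stage 5: enrichment ----------------------------------------------------
    try:
        universe = set(map(str, table.index))
        if config.pathway_path:
            db = enrich.PathwayDB.from_tsv(config.pathway_path)
        else:
            db = enrich.PathwayDB.from_annotations(processed.metabolite_meta)
        ora = enrich.hypergeometric_ora(set(hits), universe, db)
        if db.graph is not None:
            ora = ora.join(enrich.pathway_impact(set(hits), db))
        opath = outdir / "enrichment_ora.tsv"
        ora.to_csv(opath, sep="\t", index_label="pathway")
        epaths = [opath]
        if "fingerprint" in processed.metabolite_meta:
            clusters = enrich.cluster_by_similarity(
                processed.metabolite_meta["fingerprint"], config.similarity_threshold
            )
            chem = enrich.ks_cluster_test(
                clusters, table["p_median"], table["fold_change"],
                cluster_names=processed.metabolite_meta["sub_pathway"],
            )
            cpath = outdir / "enrichment_chemical.tsv"
            chem.to_csv(cpath, sep="\t")
            epaths.append(cpath)
    except Exception as e:  # noqa: BLE001
        raise stage_fail("enrich", e) from e
    record("enrich", epaths)

    # -- stage 6: network --------------------------------------------------------
    try:
        node_ids = hits if len(hits) >= 2 else list(table.nsmallest(10, "p_median").index)
        # log-transformed (pre-Pareto) values: reconstruct from untransformed
        logX = np.log(processed.untransformed[node_ids])
        net = network.build_network(
            logX, config.correlation_threshold, annotations=processed.metabolite_meta
        )
        npaths = net.write(outdir)
        hubtab = network.hubs(net, top_k=20)
        hpath = outdir / "network_hubs.tsv"
        hubtab.to_csv(hpath, sep="\t")
        npaths["hubs"] = hpath
    except Exception as e:  # noqa: BLE001
        raise stage_fail("network", e) from e
    record("network", npaths)

    # -- stage 7: validation -------------------------------------------------------
    if config.run_validation:
        try:
            shared = hits[: max(4, len(hits) // 2)] if hits else list(table.index[:4])
            synth_cfg = synthdata.SynthConfig(**{"seed": config.seed, **config.synth})
            val = synthdata.generate_validation_cohort(
                synth_cfg, shared, discovery=None if truth is None else
                synthdata.SynthCohort(matrix=raw, truth=truth, truth_blocks=pd.Series(-1, index=truth.index)),
            )
            logged = CohortMatrix(
                abundances=np.log(val.matrix.abundances),
                sample_meta=val.matrix.sample_meta,
                metabolite_meta=val.matrix.metabolite_meta,
                state=["filter", "impute", "normalize", "log"],
            )
            vtab, overlap = assoc.validate_linear(logged, "cortisol_baseline", discovery_hits=hits)
            vpath2 = outdir / "validation.tsv"
            vtab.to_csv(vpath2, sep="\t", index_label="metabolite_id")
            ovpath = outdir / "validation_overlap.json"
            ovpath.write_text(json.dumps(overlap, indent=2, default=str) + "\n")
        except Exception as e:  # noqa: BLE001
            raise stage_fail("validate", e) from e
        record("validate", [vpath2, ovpath])

    # -- stage 8: manifest ----------------------------------------------------------
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
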