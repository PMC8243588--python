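"""End-to-end orchestration: preprocess -> network -> traits -> diffexp ->
enrichment -> [preservation] -> prognostics, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexp as de
from . import enrichment as enr
from . import io as ckio
from . import preservation as pres
from . import prognostics as prog
from . import trait_stats as ts
from .network import NetworkConfig, build_network
from .preprocessing import preprocess
from .types import InputError, module_color

log = logging.getLogger("coexkit")

STAGES = ["preprocess", "network", "traits", "diffexp", "enrich", "preserve", "prognose"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    expr: str
    traits: str
    outdir: str
    seed: int
    gmt: str | None = None
    test_expr: str | None = None
    max_zero_fraction: float = 0.5
    offset: float = 0.05
    zk_threshold: float = 3.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    trait_columns: list[str] | None = None
    n_perm: int = 100
    roc_pool_size: int = 5
    combo_max_size: int = 2

    def validate(self) -> None:
        for name in ("expr", "traits", "gmt", "test_expr"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise InputError(f"config path {name}={path!r} does not exist")
        if self.seed is None:
            raise InputError("seed is mandatory")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        net = NetworkConfig(**raw.pop("network", {}))
        return cls(network=net, **raw)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the config seed and the stage name."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, outputs: list[Path], elapsed: float) -> None:
        self.stages[stage] = {
            "outputs": {p.name: _checksum(p) for p in outputs},
            "seconds": round(elapsed, 3),
        }

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "stages": self.stages,
                "warnings": self.warnings}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all stages in order, writing each stage's outputs before the next.

    A stage failure raises :class:`StageError`; outputs of completed stages
    and a partial manifest remain on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_repr = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    )
    manifest = RunManifest(config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest())
    manifest_path = outdir / "manifest.json"

    def finish(stage: str, outputs: list[Path], t0: float):
        manifest.record(stage, outputs, time.time() - t0)
        ckio.write_json(manifest.to_dict(), manifest_path)
        log.info("[%s] done (%.1fs)", stage, time.time() - t0)

    # ---- preprocess -------------------------------------------------------
    t0 = time.time()
    try:
        X = ckio.read_expression(config.expr)
        traits = ckio.read_traits(config.traits)
        ckio.check_sample_consistency(X, traits)
        cleaned, report = preprocess(
            X, config.max_zero_fraction, config.offset, config.zk_threshold
        )
        traits = traits.align(cleaned.samples)
        p_expr = outdir / "cleaned.tsv"
        p_rep = outdir / "cleaning_report.json"
        ckio.write_expression(cleaned, p_expr, float_format="%.10g")
        ckio.write_json(report.to_dict(), p_rep)
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e)
    finish("preprocess", [p_expr, p_rep], t0)

    # ---- network ----------------------------------------------------------
    t0 = time.time()
    try:
        model = build_network(cleaned, config.network)
        assign_df = pd.DataFrame(
            {
                "gene_id": model.assignment.index,
                "module_label": model.assignment.to_numpy(),
                "module_color_alias": [module_color(int(m)) for m in model.assignment],
            }
        )
        p_assign = outdir / "modules.tsv"
        assign_df.to_csv(p_assign, sep="\t", index=False)
        p_me = outdir / "eigengenes.tsv"
        me = model.eigengenes.copy()
        me.index = [f"ME{int(m)}" for m in me.index]
        me.index.name = "module"
        me.to_csv(p_me, sep="\t", float_format="%.6g")
        p_kme = outdir / "kme.tsv"
        kme = model.kme.copy()
        kme.columns = [f"ME{int(m)}" for m in kme.columns]
        kme.index.name = "gene_id"
        kme.to_csv(p_kme, sep="\t", float_format="%.6g")
    except Exception as e:  # noqa: BLE001
        raise StageError("network", e)
    finish("network", [p_assign, p_me, p_kme], t0)

    # ---- traits -----------------------------------------------------------
    t0 = time.time()
    try:
        tdf = traits.data
        cols = config.trait_columns or [
            c for c in tdf.columns if pd.api.types.is_numeric_dtype(tdf[c])
        ]
        sub = ts.SampleTraits(tdf[cols]) if cols else traits
        mt = ts.module_trait_correlation(model.eigengenes, sub)
        p_rho = outdir / "module_trait_rho.tsv"
        p_p = outdir / "module_trait_p.tsv"
        mt.rho.to_csv(p_rho, sep="\t", float_format="%.6g")
        mt.p.to_csv(p_p, sep="\t", float_format="%.6g")
        outputs = [p_rho, p_p]
        if model.eigengenes.shape[0] >= 2:
            Z, leaves = ts.me_dendrogram(model.eigengenes)
            p_nwk = outdir / "me_dendrogram.nwk"
            p_nwk.write_text(
                ts.linkage_to_newick(Z, [f"ME{int(m)}" for m in leaves]) + "\n"
            )
            relapse = tdf["relapse"] if "relapse" in tdf.columns else None
            labels, summary = ts.cluster_samples_by_me(
                model.eigengenes, relapse=relapse
            )
            p_clust = outdir / "sample_clusters.tsv"
            pd.DataFrame({"sample_id": labels.index, "cluster": labels.to_numpy()}).to_csv(
                p_clust, sep="\t", index=False
            )
            p_csum = outdir / "sample_cluster_summary.tsv"
            summary.to_csv(p_csum, sep="\t")
            outputs += [p_nwk, p_clust, p_csum]
        conf_cols = [c for c in ("sex", "age") if c in tdf.columns]
        if conf_cols and model.eigengenes.shape[0] >= 1:
            decomp = ts.variance_partition(model.eigengenes, tdf[conf_cols])
            p_var = outdir / "variance_partition.tsv"
            pd.DataFrame(
                [
                    {"unit": d.unit_id, **d.fractions, "residual": d.residual}
                    for d in decomp
                ]
            ).to_csv(p_var, sep="\t", index=False, float_format="%.6g")
            outputs.append(p_var)
    except Exception as e:  # noqa: BLE001
        raise StageError("traits", e)
    finish("traits", outputs, t0)

    # ---- diffexp ----------------------------------------------------------
    t0 = time.time()
    try:
        groups = de.binet_relapse_groups(traits.data)
        records = []
        V = cleaned.values
        garr = groups.loc[cleaned.samples].to_numpy()
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            for gi, gene in enumerate(cleaned.genes):
                # focal pair only: the studentized-range tail is ~10 ms/call
                rec = de.anova_tukey(
                    V[gi], garr, gene_id=gene,
                    module=int(model.assignment.get(gene, 0)),
                    pairs=[de.FOCAL_PAIR],
                )
                records.append(rec)
        table = de.volcano_table(records)
        p_de = outdir / "diffexp.tsv"
        de_df = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "F": r.F,
                    "anova_p": r.anova_p,
                    "tukey_p_focal": r.focal_p(),
                    "lfc": r.lfc,
                    "module": r.module,
                }
                for r in records
            ]
        )
        de_df.to_csv(p_de, sep="\t", index=False, float_format="%.6g")
        p_volc = outdir / "volcano.tsv"
        table.to_csv(p_volc, sep="\t", index=False, float_format="%.6g")
        hubs = de.select_biomarkers(records, model.kme, model.assignment)
        p_hub = outdir / "biomarkers.json"
        ckio.write_json({str(m): g for m, g in hubs.items()}, p_hub)
    except Exception as e:  # noqa: BLE001
        raise StageError("diffexp", e)
    finish("diffexp", [p_de, p_volc, p_hub], t0)

    # ---- enrich -----------------------------------------------------------
    if config.gmt:
        t0 = time.time()
        try:
            sets = ckio.read_gmt(config.gmt)
            background = cleaned.genes
            outputs = []
            for m in model.module_labels:
                query = model.module_genes(m)
                recs = enr.fisher_enrichment(query, sets, background)
                p_enr = outdir / f"enrichment_M{m}.tsv"
                enr.enrichment_frame(recs).to_csv(
                    p_enr, sep="\t", index=False, float_format="%.6g"
                )
                outputs.append(p_enr)
        except Exception as e:  # noqa: BLE001
            raise StageError("enrich", e)
        finish("enrich", outputs, t0)

    # ---- preserve ---------------------------------------------------------
    if config.test_expr:
        t0 = time.time()
        try:
            test = ckio.read_expression(config.test_expr)
            test_clean, _ = preprocess(
                test, config.max_zero_fraction, config.offset, config.zk_threshold
            )
            rep = pres.preservation_stats(
                cleaned, test_clean, model.assignment,
                n_perm=config.n_perm, seed=stage_seed(config.seed, "preserve"),
            )
            p_pres = outdir / "preservation.tsv"
            rep.frame().to_csv(p_pres, sep="\t", index=False, float_format="%.6g")
            p_pres_j = outdir / "preservation.json"
            ckio.write_json(
                json.loads(rep.frame().to_json(orient="records")), p_pres_j
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("preserve", e)
        finish("preserve", [p_pres, p_pres_j], t0)

    # ---- prognose ---------------------------------------------------------
    t0 = time.time()
    try:
        tdf = traits.data
        outputs = []
        if {"relapse", "relapse_interval"} <= set(tdf.columns):
            rfs = prog.survival_records_from_traits(tdf, prog.RELAPSE_FREE_SURVIVAL)
            relapse_labels = tdf["relapse"].astype(int)
            # Table-4-shaped per-gene ROC for the top biomarker genes
            pool = [g for gs in hubs.values() for g in gs]
            if not pool:
                focal = de_df.dropna(subset=["tukey_p_focal"])
                pool = list(
                    focal.sort_values("tukey_p_focal")["gene_id"].head(
                        config.roc_pool_size * 2
                    )
                )
            rows = []
            for g in pool:
                expr_row = cleaned.data.loc[g, tdf.index].to_numpy()
                r = prog.roc_auc(expr_row, relapse_labels.to_numpy(), marker_name=g)
                rows.append(
                    {"gene": g, "AUC": r.auc, "Z": r.z, "p": r.p,
                     "module": int(model.assignment.get(g, 0))}
                )
            p_roc = outdir / "roc_genes.tsv"
            pd.DataFrame(rows).to_csv(p_roc, sep="\t", index=False,
                                      float_format="%.6g")
            outputs.append(p_roc)

            # combination screening over z-scored expression
            up = [r["gene"] for r in sorted(rows, key=lambda r: -r["AUC"])][: config.roc_pool_size]
            down_df = de_df.dropna(subset=["lfc"]).sort_values("lfc")
            down = [g for g in down_df["gene_id"] if g not in up][: config.roc_pool_size]
            if up and down:
                Vz = cleaned.data.sub(cleaned.data.mean(axis=1), axis=0)
                Vz = Vz.div(cleaned.data.std(axis=1, ddof=1).replace(0, 1), axis=0)
                combos = prog.screen_combinations(
                    Vz, up, down, rfs, max_size=config.combo_max_size
                )
                combo_rows = [
                    {
                        "numerator": "+".join(c.numerator_genes),
                        "denominator": "+".join(c.denominator_genes),
                        **{f"auc_{h}": a for h, a in c.auc_by_horizon.items()},
                    }
                    for c in combos
                ]
                p_combo = outdir / "combination_auc.tsv"
                pd.DataFrame(combo_rows).to_csv(
                    p_combo, sep="\t", index=False, float_format="%.6g"
                )
                outputs.append(p_combo)

            # KM + cutpoint for the strongest marker
            if pool:
                marker = pool[0]
                expr_row = cleaned.data.loc[marker, tdf.index]
                cut = prog.optimal_cutpoint(expr_row, rfs)
                if cut.get("status") == "ok":
                    cut_out = {
                        k: v for k, v in cut.items() if k != "labels"
                    }
                    cut_out["marker"] = marker
                    p_cut = outdir / "cutpoint.json"
                    ckio.write_json(cut_out, p_cut)
                    km_hi = prog.km_curve(
                        [r for r in rfs if cut["labels"][r.sample_id] == "high"]
                    )
                    km_lo = prog.km_curve(
                        [r for r in rfs if cut["labels"][r.sample_id] == "low"]
                    )
                    p_km = outdir / "km_curves.tsv"
                    km_hi["group"] = "high"
                    km_lo["group"] = "low"
                    pd.concat([km_hi, km_lo]).to_csv(
                        p_km, sep="\t", index=False, float_format="%.6g"
                    )
                    outputs += [p_cut, p_km]
    except Exception as e:  # noqa: BLE001
        raise StageError("prognose", e)
    finish("prognose", outputs, t0)

    return manifest
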