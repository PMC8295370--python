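"""End-to-end orchestration: simulate -> behavior -> fit/decode ->
reinstatement -> connectivity -> stats, with a reproducibility manifest.

A run is driven by a :class:`RunConfig` (loadable from YAML).  One global
seed is expanded into per-stage child seeds with ``numpy.random.SeedSequence``
so stages can be rerun independently yet bit-identically; every stage
writes TSV/JSON artifacts plus a manifest recording parameters, seeds and
content hashes.
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

from . import behavior, connectivity, encoding_models, reinstatement, stats
from .synthetic_data import SimulationConfig, simulate_subject, \
    write_electrodes_tsv, write_events_tsv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "behavior", "fit", "reinstate", "connectivity", "stats")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "runs/demo"
    seed: int = 0
    n_subjects: int = 2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = STAGES
    models: tuple[str, ...] = ("content", "context")
    networks: tuple[str, ...] = ("PM", "AT")
    k_electrodes: int = 5
    n_boot: int = 20
    n_null: int = 200
    n_perm: int = 500
    fwhm_ms: float = 7.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["models"] = list(self.models)
        d["networks"] = list(self.networks)
        return d


def stage_seed(base_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage child seed below 2**31."""
    h = hashlib.sha256(f"{base_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages; returns the run directory.

    Reruns with an identical config are bit-identical (same manifest
    hashes).  A stage failure aborts with a stage-tagged error; artifacts
    of completed stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "artifacts": {}}

    subjects = []
    try:
        if "simulate" in config.stages:
            for i in range(config.n_subjects):
                seed = stage_seed(config.seed, "simulate", i)
                sub = simulate_subject(config.simulation, seed=seed)
                subjects.append(sub)
                write_events_tsv(sub, out / f"events_S{i:03d}.tsv", f"S{i:03d}")
                write_electrodes_tsv(sub, out / f"electrodes_S{i:03d}.tsv")
            manifest["stages"]["simulate"] = {
                "n_subjects": len(subjects),
                "seeds": [stage_seed(config.seed, "simulate", i)
                          for i in range(config.n_subjects)],
            }

        if "behavior" in config.stages and subjects:
            rows = []
            for i, sub in enumerate(subjects):
                fs = behavior.structure_matched_z(
                    sub.recalls, sub.structures, n_null=config.n_null,
                    seed=stage_seed(config.seed, "behavior", i))
                rows.append({"subject": f"S{i:03d}", "temporal": fs.temporal,
                             "categorical": fs.categorical,
                             "temporal_z": fs.temporal_z,
                             "categorical_z": fs.categorical_z})
            factors = pd.DataFrame(rows)
            factors.to_csv(out / "factors.tsv", sep="\t", index=False)
            all_events = pd.concat(
                [s.events.assign(subject=f"S{i:03d}")
                 for i, s in enumerate(subjects)], ignore_index=True)
            if len(subjects) >= 2:
                summary = behavior.recall_summary(all_events)
                payload = {
                    "overall_recall": summary["overall_recall"],
                    "by_position": summary["by_position"].to_dict("records"),
                    "by_category": summary["by_category"].to_dict("records"),
                }
                (out / "group_summary.json").write_text(
                    json.dumps(payload, indent=2, default=str))
            manifest["stages"]["behavior"] = {"n_subjects": len(rows)}

        series_store: dict = {}
        if {"fit", "reinstate"} & set(config.stages) and subjects:
            auc_rows = []
            series_rows = []
            for i, sub in enumerate(subjects):
                emb = sub.truth.true_embeddings
                designs = {}
                if "content" in config.models:
                    designs["content"] = encoding_models.build_content_design(
                        sub.events, emb, sub.truth.word_categories)
                if "context" in config.models:
                    designs["context"] = encoding_models.build_context_design(
                        sub.events, sub.config.list_length)
                for kind, design in designs.items():
                    seed = stage_seed(config.seed, f"fit-{kind}", i)
                    boot = encoding_models.bootstrap_electrode_auc(
                        sub.encoding, design, sub.config.network_labels,
                        networks=config.networks, k=config.k_electrodes,
                        n_boot=config.n_boot, seed=seed)
                    for net, res in boot.items():
                        auc_rows.append({"subject": f"S{i:03d}", "model": kind,
                                         "network": net, "auc": res["mean"]})
                    if "reinstate" in config.stages:
                        label_col = ("category" if kind == "content"
                                     else "study_position")
                        ev = sub.retrieval_events
                        if kind == "content":
                            ids = list(design.class_ids)
                            labels = ev["category"].map(ids.index).to_numpy()
                        else:
                            labels = ev["study_position"].to_numpy() - 1
                        rein = reinstatement.bootstrap_reinstatement(
                            sub.encoding, sub.retrieval, design, labels,
                            sub.config.network_labels,
                            recalled_words=ev["item"].to_numpy(),
                            networks=config.networks, k=config.k_electrodes,
                            n_boot=max(2, config.n_boot // 4),
                            seed=stage_seed(config.seed, f"rein-{kind}", i))
                        for net, ser in rein.items():
                            sm = reinstatement.smooth_series(
                                ser, fwhm_ms=config.fwhm_ms)
                            series_store.setdefault((kind, net), []).append(sm.auc)
                            for t, a in zip(sm.time_ms, sm.auc):
                                series_rows.append({
                                    "subject": f"S{i:03d}", "model": kind,
                                    "network": net, "time_ms": t, "auc": a})
            if auc_rows:
                pd.DataFrame(auc_rows).to_csv(out / "encoding_auc.tsv",
                                              sep="\t", index=False)
                manifest["stages"]["fit"] = {"n_rows": len(auc_rows)}
            if series_rows:
                pd.DataFrame(series_rows).to_csv(out / "reinstatement.tsv",
                                                 sep="\t", index=False)
                manifest["stages"]["reinstate"] = {"n_rows": len(series_rows)}

        if "connectivity" in config.stages and subjects:
            con_rows = []
            for i, sub in enumerate(subjects):
                pairs = connectivity.build_pairs(sub.electrodes)
                est = connectivity.distance_matched_bootstrap(
                    sub.encoding, pairs, n_boot=max(50, config.n_boot),
                    seed=stage_seed(config.seed, "connectivity", i))
                for net, contrast in est.contrast.items():
                    for fi, c in enumerate(contrast):
                        con_rows.append({"subject": f"S{i:03d}", "network": net,
                                         "freq_index": fi, "contrast": c,
                                         "excluded": est.excluded})
            pd.DataFrame(con_rows).to_csv(out / "connectivity.tsv", sep="\t",
                                          index=False)
            manifest["stages"]["connectivity"] = {"n_rows": len(con_rows)}

        if "stats" in config.stages and series_store:
            stat_out = {}
            for (kind, net), series in series_store.items():
                arr = np.stack(series)
                if arr.shape[0] >= 2:
                    res = stats.tfce_permutation_test(
                        arr, n_perm=config.n_perm, chance=0.5,
                        seed=stage_seed(config.seed, f"stats-{kind}-{net}"))
                    stat_out[f"{kind}-{net}"] = {
                        "p_min": float(res.p_corrected.min()),
                        "n_significant": int(res.significant.sum()),
                    }
            (out / "stats.json").write_text(json.dumps(stat_out, indent=2))
            manifest["stages"]["stats"] = stat_out
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["artifacts"][f.name] = _hash_file(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out
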