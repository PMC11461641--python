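"""End-to-end pipeline driver with a run manifest.

``run_pipeline`` executes simulate -> classify -> stats -> immune in order,
writes every stage output under one directory, and records a manifest with
the config hash, seed, package version and a checksum per output file.
Identical (config, seed) yield identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError
from .immune import annotate_and_count, demux_hashtags, qc_filter_nuclei, signature_score
from .io import (
    bulk_config_from_dict,
    cohort_config_from_dict,
    load_config,
    nuclei_config_from_dict,
    write_segment_profiles,
)
from .mismatch import MismatchThresholds, cohort_assign
from .stats import delta_delta_ct, mismatch_association_suite, report_to_frame
from .synthetic import (
    BulkConfig,
    CohortConfig,
    NucleiConfig,
    simulate_bulk_expression,
    simulate_cohort,
    simulate_nuclei,
)

logger = logging.getLogger(__name__)

REQUIRED_BLOCKS = ("cohort", "bulk", "nuclei")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def record(self, path: Path, root: Path) -> None:
        self.files[str(path.relative_to(root))] = _sha256(path)

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "version": self.version, "files": self.files,
                "started": self.started, "finished": self.finished}


def parse_config(config: dict | str | Path | None) -> dict:
    """Resolve a config mapping (or YAML path) into typed config objects.

    A supplied mapping must contain the ``cohort``, ``bulk`` and ``nuclei``
    blocks; ``None`` means package defaults everywhere.
    """
    if config is None:
        return {"cohort": CohortConfig(), "bulk": BulkConfig(),
                "nuclei": NucleiConfig(), "pipeline": {}, "_raw": {}}
    raw = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    for block in REQUIRED_BLOCKS:
        if block not in raw:
            raise ConfigError(f"missing required config block {block!r}")
    return {
        "cohort": cohort_config_from_dict(raw["cohort"]),
        "bulk": bulk_config_from_dict(raw["bulk"]),
        "nuclei": nuclei_config_from_dict(raw["nuclei"]),
        "pipeline": dict(raw.get("pipeline", {})),
        "_raw": raw,
    }


def run_pipeline(
    config: dict | str | Path | None,
    outdir: str | Path,
    seed: int = 0,
) -> RunManifest:
    """Run every stage and write outputs + ``manifest.json`` under ``outdir``."""
    cfgs = parse_config(config)
    cohort_cfg: CohortConfig = cfgs["cohort"]
    bulk_cfg: BulkConfig = cfgs["bulk"]
    nuclei_cfg: NucleiConfig = cfgs["nuclei"]
    popts = cfgs["pipeline"]
    n_cells = int(popts.get("n_cells_per_arm", 400))
    n_bulk = int(popts.get("n_bulk_per_arm", 4))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(cfgs["_raw"]), seed=int(seed), version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )

    # stage 1: simulate
    logger.info("stage simulate: n_match=%d n_mismatch=%d seed=%d",
                cohort_cfg.n_match, cohort_cfg.n_mismatch, seed)
    cohort = simulate_cohort(cohort_cfg, seed=seed)
    cohort.animals.to_csv(outdir / "animals.csv", index=False)
    write_segment_profiles(cohort.profiles, outdir / "segments.csv")
    cohort.biomarkers.to_csv(outdir / "biomarkers.csv", index=False)
    cohort.ct.to_csv(outdir / "qpcr_ct.csv", index=False)

    # stage 2: classify
    logger.info("stage classify: thresholds=default")
    assignments, prevalence = cohort_assign(cohort.profiles, MismatchThresholds())
    assignments.to_csv(outdir / "groups.csv", index=False)
    with open(outdir / "prevalence.json", "w", encoding="utf-8") as fh:
        json.dump(prevalence, fh, indent=1)

    # stage 3: statistics
    logger.info("stage stats")
    animals = cohort.animals.merge(assignments[["animal_id", "group"]], on="animal_id")
    report = mismatch_association_suite(
        animals, cohort.profiles, cohort_cfg.infarct_territory
    )
    report_to_frame(report).to_csv(outdir / "stats_report.csv", index=False)
    folds = pd.concat(
        [delta_delta_ct(cohort.ct, target=t) for t in ("CD45", "CD68", "TNFa")],
        ignore_index=True,
    )
    folds.drop(columns=["reference_genes"]).to_csv(outdir / "qpcr_folds.csv", index=False)

    # stage 4: immune
    logger.info("stage immune: %d cells/arm, %d bulk samples/arm", n_cells, n_bulk)
    bulk = simulate_bulk_expression(bulk_cfg, n_per_arm=n_bulk, seed=seed)
    scored = signature_score(bulk.counts, bulk_cfg.signatures)
    scored["zscores"].to_csv(outdir / "signature_zscores.csv")

    import anndata as ad

    arms = []
    for i, (region, group) in enumerate([("Border", "Match"), ("Border", "Mismatch")]):
        arms.append(simulate_nuclei(nuclei_cfg, region, group, n_cells, seed=seed + i))
    nuclei = ad.concat(arms, merge="same")
    nuclei.obs_names_make_unique()
    filtered, qc_report = qc_filter_nuclei(nuclei)
    with open(outdir / "qc_report.json", "w", encoding="utf-8") as fh:
        json.dump(qc_report, fh, indent=1)
    demux, _ = demux_hashtags(filtered.obsm["hto"], seed=seed)
    demux.to_csv(outdir / "hashtag_assignments.csv")
    labels, counts_table = annotate_and_count(filtered, nuclei_cfg.signatures)
    counts_table.to_csv(outdir / "cell_type_counts.csv", index=False)

    for f in sorted(outdir.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.record(f, outdir)
    manifest.finished = datetime.now(timezone.utc).isoformat()
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)
    return manifest
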