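"""Readers and writers for the delimited/Matrix-Market formats shared by
all pipeline stages.

Conventions: comma-separated UTF-8 text with a header row, '.' decimal,
percents on the 0-100 scale.  Count matrices go to Matrix Market triplets
with side-car gene and sample/cell tables; signatures are two-column
(cell_type, gene) tables.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as sio
from scipy import sparse

from .errors import ConfigError, ValidationError
from .polarmap import N_SEGMENTS, SegmentProfile, Territory
from .signatures import SignatureSet
from .synthetic import BulkConfig, CohortConfig, NucleiConfig

_SEG = [f"s{i:02d}" for i in range(1, N_SEGMENTS + 1)]


# ---------------------------------------------------------------------------
# segment profiles


def write_segment_profiles(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row: dict = {"animal_id": p.animal_id, "timepoint": p.timepoint,
                     "mvo_extent": p.mvo_extent}
        for prefix, vec in (("tm", p.transmurality), ("raw", p.uptake_raw),
                            ("ct", p.contractility)):
            row.update({f"{prefix}_{s}": v for s, v in zip(_SEG, vec)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_segment_profiles(path: str | Path) -> list[SegmentProfile]:
    df = pd.read_csv(path)
    required = {"animal_id", "timepoint", "mvo_extent"}
    if not required <= set(df.columns):
        raise ValidationError(f"segment table missing columns {required - set(df.columns)}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            SegmentProfile(
                animal_id=str(row["animal_id"]),
                timepoint=str(row["timepoint"]),
                transmurality=row[[f"tm_{s}" for s in _SEG]].to_numpy(dtype=float),
                uptake_raw=row[[f"raw_{s}" for s in _SEG]].to_numpy(dtype=float),
                contractility=row[[f"ct_{s}" for s in _SEG]].to_numpy(dtype=float),
                mvo_extent=float(row["mvo_extent"]),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# count matrices (genes x samples/cells)


def write_counts(counts: pd.DataFrame, outdir: str | Path,
                 meta: pd.DataFrame | None = None) -> None:
    """Write a gene x sample count table as MTX + index side-cars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / "counts.mtx"), sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index, name="gene").to_csv(outdir / "genes.csv", index=False)
    cols = pd.DataFrame({"sample": counts.columns})
    if meta is not None:
        cols = cols.join(meta.reset_index(drop=True))
    cols.to_csv(outdir / "samples.csv", index=False)


def read_counts(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    mat = sio.mmread(str(indir / "counts.mtx"))
    genes = pd.read_csv(indir / "genes.csv")["gene"].tolist()
    samples = pd.read_csv(indir / "samples.csv")
    counts = pd.DataFrame(
        np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.int64),
        index=genes, columns=samples["sample"].tolist(),
    )
    meta = samples.set_index("sample")
    return counts, meta


def write_cellmatrix(adata, outdir: str | Path) -> None:
    """Write an AnnData (cells x genes) as MTX plus obs/var/hto tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / "counts.mtx"), sparse.csr_matrix(adata.X))
    pd.Series(adata.var_names, name="gene").to_csv(outdir / "genes.csv", index=False)
    adata.obs.rename_axis("cell").to_csv(outdir / "cells.csv")
    if "hto" in adata.obsm:
        adata.obsm["hto"].rename_axis("cell").to_csv(outdir / "hto.csv")


def read_cellmatrix(indir: str | Path):
    import anndata as ad

    indir = Path(indir)
    mat = sparse.csr_matrix(sio.mmread(str(indir / "counts.mtx")))
    genes = pd.read_csv(indir / "genes.csv")["gene"].tolist()
    obs = pd.read_csv(indir / "cells.csv", index_col="cell")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=mat, obs=obs, var=pd.DataFrame(index=genes))
    hto_path = indir / "hto.csv"
    if hto_path.exists():
        hto = pd.read_csv(hto_path, index_col="cell").set_axis(adata.obs_names, axis=0)
        hto.index.name = None
        adata.obsm["hto"] = hto
    return adata


# ---------------------------------------------------------------------------
# signatures


def write_signatures(sigs: SignatureSet, path: str | Path) -> None:
    rows = [{"cell_type": t, "gene": g} for t in sigs.cell_types for g in sigs[t]]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_signatures(path: str | Path, provenance: str | None = None) -> SignatureSet:
    df = pd.read_csv(path)
    if not {"cell_type", "gene"} <= set(df.columns):
        raise ValidationError("signature file needs cell_type and gene columns")
    sig: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        sig.setdefault(str(row["cell_type"]), []).append(str(row["gene"]))
    return SignatureSet(sig, provenance=provenance or str(path))


# ---------------------------------------------------------------------------
# configuration files


def _join_keys(d: dict) -> dict:
    return {"|".join(k) if isinstance(k, tuple) else k: v for k, v in d.items()}


def _split_keys(d: dict) -> dict:
    return {tuple(k.split("|")) if isinstance(k, str) and "|" in k else k: v
            for k, v in d.items()}


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def cohort_config_to_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["infarct_territory"] = {"name": cfg.infarct_territory.name,
                              "segment_ids": list(cfg.infarct_territory.segment_ids)}
    d["ct_shift"] = {g: _join_keys(m) for g, m in cfg.ct_shift.items()}
    return _listify(d)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "infarct_territory" in d and isinstance(d["infarct_territory"], dict):
        t = d["infarct_territory"]
        d["infarct_territory"] = Territory(t["name"], tuple(t["segment_ids"]))
    if "ct_shift" in d:
        d["ct_shift"] = {g: _split_keys(dict(m)) for g, m in d["ct_shift"].items()}
    for key, val in list(d.items()):
        if isinstance(val, list) and len(val) == 2 and all(
            isinstance(v, (int, float)) for v in val
        ):
            d[key] = tuple(val)
        elif isinstance(val, dict):
            d[key] = {
                k: tuple(v) if isinstance(v, list) and len(v) == 2 else v
                for k, v in val.items()
            }
    unknown = set(d) - set(CohortConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(**d)


def bulk_config_from_dict(d: dict) -> BulkConfig:
    d = dict(d)
    if "signatures" in d and isinstance(d["signatures"], dict):
        d["signatures"] = SignatureSet(d["signatures"], provenance="config")
    if "effects" in d:
        d["effects"] = {t: _split_keys(dict(m)) for t, m in d["effects"].items()}
    unknown = set(d) - set(BulkConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown bulk config keys: {sorted(unknown)}")
    return BulkConfig(**d)


def nuclei_config_from_dict(d: dict) -> NucleiConfig:
    d = dict(d)
    if "signatures" in d and isinstance(d["signatures"], dict):
        d["signatures"] = SignatureSet(d["signatures"], provenance="config")
    if "proportions" in d:
        d["proportions"] = _split_keys(dict(d["proportions"]))
    if "mito_beta" in d:
        d["mito_beta"] = {k: tuple(v) for k, v in d["mito_beta"].items()}
    unknown = set(d) - set(NucleiConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown nuclei config keys: {sorted(unknown)}")
    return NucleiConfig(**d)


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_listify(cfg), fh, sort_keys=True)
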