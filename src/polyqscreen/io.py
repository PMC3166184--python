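"""File I/O: FASTA proteomes, 16-bit field images, plate maps, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .image_quant import FieldImage
from .orthology import SequenceRecord
from .simulate import RenderedField


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path, organism: str) -> list[SequenceRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    return [
        SequenceRecord(id=rec.id, organism=organism, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def field_image_paths(
    image_dir: str | Path, experiment_id: str, well: str, field_idx: int
) -> tuple[Path, Path]:
    stem = f"{experiment_id}_{well}_f{field_idx:02d}"
    d = Path(image_dir)
    return d / f"{stem}_dapi.tif", d / f"{stem}_gfp.tif"


def write_field_images(
    field: RenderedField,
    image_dir: str | Path,
    experiment_id: str,
    well: str,
    field_idx: int,
) -> None:
    p_dapi, p_gfp = field_image_paths(image_dir, experiment_id, well, field_idx)
    p_dapi.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(p_dapi, _to_uint16(field.nuclei_channel))
    tifffile.imwrite(p_gfp, _to_uint16(field.gfp_channel))


def read_field_images(
    image_dir: str | Path, experiment_id: str, well: str, n_fields: int
) -> list[FieldImage]:
    fields = []
    for k in range(n_fields):
        p_dapi, p_gfp = field_image_paths(image_dir, experiment_id, well, k)
        if not p_dapi.exists() or not p_gfp.exists():
            raise FileNotFoundError(f"missing field images for {experiment_id}/{well}")
        fields.append(
            FieldImage(
                nuclei_channel=tifffile.imread(p_dapi).astype(float),
                gfp_channel=tifffile.imread(p_gfp).astype(float),
                field_id=f"f{k:02d}",
                well_id=well,
            )
        )
    return fields


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def read_wells_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"well table not found: {path}")
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    needed = {"experiment_id", "round", "well", "gene", "construct_id", "role",
              "raw_pct"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["raw_pct"] = pd.to_numeric(df["raw_pct"], errors="coerce")
    return df
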