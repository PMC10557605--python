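"""Readers and writers for the on-disk formats the pipeline exchanges.

Matrices go to MatrixMarket (.mtx) with barcodes.tsv / features.tsv sidecars;
peaks to BED3+name (0-based half-open); variants to a VCF-like TSV (1-based);
gene models to a TSS TSV; PWMs to JASPAR text; ground truth to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Set

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import CreAtlas, GroundTruth, MultiomeMatrices


def write_multiome(m: MultiomeMatrices, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "atac.mtx", sparse.csr_matrix(m.atac))
    spio.mmwrite(out / "rna.mtx", sparse.csr_matrix(m.rna))
    pd.Series(m.barcodes).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    m.peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    m.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    m.cells.to_csv(out / "cells.tsv", sep="\t", index=False)


def read_multiome(outdir: str | Path) -> MultiomeMatrices:
    out = Path(outdir)
    atac = np.asarray(spio.mmread(out / "atac.mtx").todense()).astype(np.int64)
    rna = np.asarray(spio.mmread(out / "rna.mtx").todense()).astype(np.int64)
    barcodes = pd.read_csv(out / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    peaks = pd.read_csv(out / "peaks.tsv", sep="\t")
    genes = pd.read_csv(out / "genes.tsv", sep="\t")
    cells = pd.read_csv(out / "cells.tsv", sep="\t")
    return MultiomeMatrices(atac=atac, rna=rna, barcodes=barcodes, peaks=peaks, genes=genes, cells=cells)


def write_atlas_beds(atlas: CreAtlas, outdir: str | Path) -> None:
    """One BED3+name file per cell type listing the peaks detected in it."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    types: Set[str] = set()
    for s in atlas.detected_in.values():
        types |= s
    peaks = atlas.peaks.set_index("name")
    for t in sorted(types):
        safe = t.replace("/", "_").replace(" ", "_")
        with open(out / f"peaks.{safe}.bed", "w") as fh:
            for name, row in peaks.iterrows():
                if t in atlas.detected_in[name]:
                    fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\n")


def read_atlas_beds(outdir: str | Path, type_names: Dict[str, str] | None = None) -> CreAtlas:
    """Assemble a CreAtlas from per-cell-type BED files (peaks.<type>.bed).

    type_names maps the sanitized file token back to the display name when
    they differ (e.g. 'AT1_AT2' -> 'AT1/AT2').
    """
    out = Path(outdir)
    detected: Dict[str, Set[str]] = {}
    rows = {}
    for bed in sorted(out.glob("peaks.*.bed")):
        token = bed.name[len("peaks.") : -len(".bed")]
        t = (type_names or {}).get(token, token)
        for line in bed.read_text().splitlines():
            chrom, start, end, name = line.split("\t")
            rows[name] = (chrom, int(start), int(end))
            detected.setdefault(name, set()).add(t)
    peaks = pd.DataFrame(
        [(n, c, s, e) for n, (c, s, e) in sorted(rows.items())],
        columns=["name", "chrom", "start", "end"],
    )
    return CreAtlas(peaks=peaks, detected_in=detected)


def write_variants(variants: pd.DataFrame, path: str | Path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pwms_jaspar(pwms: Dict[str, np.ndarray], path: str | Path) -> None:
    """JASPAR text: >ID NAME then one row per base of bracketed counts."""
    with open(path, "w") as fh:
        for tf, pwm in pwms.items():
            fh.write(f">{tf} {tf}\n")
            counts = np.round(pwm * 100).astype(int)
            for b, base in enumerate("ACGT"):
                row = " ".join(str(c) for c in counts[:, b])
                fh.write(f"{base}  [ {row} ]\n")


def read_pwms_jaspar(path: str | Path) -> Dict[str, np.ndarray]:
    pwms: Dict[str, np.ndarray] = {}
    name = None
    rows: Dict[str, list] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                pwms[name] = _assemble_pwm(rows)
            name = line[1:].split()[0]
            rows = {}
        elif line.strip():
            base = line.split()[0]
            inner = line[line.index("[") + 1 : line.index("]")]
            rows[base] = [float(x) for x in inner.split()]
    if name is not None:
        pwms[name] = _assemble_pwm(rows)
    return pwms


def _assemble_pwm(rows: Dict[str, list]) -> np.ndarray:
    mat = np.array([rows[b] for b in "ACGT"], dtype=float).T
    mat = mat + 1e-6
    return mat / mat.sum(axis=1, keepdims=True)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def write_insertions(track, path: str | Path) -> None:
    """Footprint insertions as a TSV of (site, position, count)."""
    n_sites, length = track.site_counts.shape
    sites = np.repeat(np.arange(n_sites), length)
    poss = np.tile(track.positions, n_sites)
    pd.DataFrame(
        {"site": sites, "position": poss, "count": track.site_counts.ravel()}
    ).to_csv(path, sep="\t", index=False)
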