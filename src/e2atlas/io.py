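"""Readers and writers for the pipeline's plain-text and TIFF interfaces.

Matrices travel as TSV with a header row of sample ids plus a sidecar
sample-metadata TSV (sample, condition, batch, replicate, is_control);
spectral counts as long-format TSV; sequences as FASTA; truth as JSON;
images as 16-bit grayscale TIFF (one file per channel or a 3-page stack).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .differential_omics import AbundanceMatrix, ExpressionMatrix, ModulationCalls
from .import_imaging import CHANNEL_NAMES, MultiChannelImage
from .interactome_scoring import SpectralCountTable
from .peroxisome_panel import AnnotationSet


# ---------------------------------------------------------------------------
# abundance / expression matrices
# ---------------------------------------------------------------------------

def write_abundance(matrix: AbundanceMatrix, values_path, meta_path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.sample_meta.to_csv(meta_path, sep="\t")


def read_abundance(values_path, meta_path) -> AbundanceMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = read_sample_meta(meta_path)
    return AbundanceMatrix(values=values, sample_meta=meta)


def write_expression(matrix: ExpressionMatrix, values_path, meta_path) -> None:
    matrix.tpm.to_csv(values_path, sep="\t")
    matrix.sample_meta.to_csv(meta_path, sep="\t")


def read_expression(values_path, meta_path) -> ExpressionMatrix:
    tpm = pd.read_csv(values_path, sep="\t", index_col=0)
    return ExpressionMatrix(tpm=tpm, sample_meta=read_sample_meta(meta_path))


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta["is_control"].dtype != bool:
        meta["is_control"] = meta["is_control"].astype(str).str.lower().isin(
            {"true", "1", "yes"})
    return meta


# ---------------------------------------------------------------------------
# truth, calls, annotation
# ---------------------------------------------------------------------------

def write_truth_json(effects: dict[tuple[str, str], float], path,
                     mrna_concordance: float | None = None) -> None:
    payload = {
        "effects": [{"condition": c, "protein": p, "log2fc": e}
                    for (c, p), e in sorted(effects.items())],
    }
    if mrna_concordance is not None:
        payload["mrna_concordance"] = mrna_concordance
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> tuple[dict[tuple[str, str], float], float | None]:
    payload = json.loads(Path(path).read_text())
    effects = {(row["condition"], row["protein"]): row["log2fc"]
               for row in payload["effects"]}
    return effects, payload.get("mrna_concordance")


def write_calls(calls: ModulationCalls, path) -> None:
    """Long-format TSV (protein, condition, direction, txn_independent, ...)
    with the thresholds recorded verbatim in header comments."""
    with open(path, "w") as fh:
        fh.write(f"# alpha={calls.alpha}\n# fc={calls.fc}\n"
                 f"# test={calls.test}\n# rna_test={calls.rna_test}\n")
        calls.table.to_csv(fh, sep="\t", index=False)


def read_calls(path) -> ModulationCalls:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
        table = pd.read_csv(fh, sep="\t")
    return ModulationCalls(table=table,
                           alpha=float(meta.get("alpha", 0.05)),
                           fc=float(meta.get("fc", 0.2)),
                           test=meta.get("test", "student"),
                           rna_test=meta.get("rna_test", "dunn"))


def read_annotation(path) -> AnnotationSet:
    """Two-column TSV: id, is_pex (boolean-ish)."""
    table = pd.read_csv(path, sep="\t")
    flags = table["is_pex"].astype(str).str.lower().isin({"true", "1", "yes"})
    return AnnotationSet(members=set(table["id"]),
                         is_pex=set(table.loc[flags, "id"]),
                         source=str(path))


# ---------------------------------------------------------------------------
# spectral counts, lengths, networks
# ---------------------------------------------------------------------------

def write_spectral_counts(table: SpectralCountTable, counts_path,
                          lengths_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index=False)
    table.lengths.rename_axis("protein").to_csv(lengths_path, sep="\t")


def read_spectral_counts(counts_path, lengths_path) -> SpectralCountTable:
    counts = pd.read_csv(counts_path, sep="\t")
    lengths = read_lengths(lengths_path)
    return SpectralCountTable(counts=counts, lengths=lengths)


def read_lengths(path) -> pd.Series:
    """Protein lengths from a FASTA file or a two-column TSV."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return pd.Series(lengths, name="length")
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.iloc[:, 0].rename("length")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_network_text(net, path) -> None:
    """Simple graph-exchange text: a node block then an edge block."""
    with open(path, "w") as fh:
        fh.write("#nodes\tid\trole\n")
        for node, data in sorted(net.nodes(data=True)):
            fh.write(f"node\t{node}\t{data.get('role', 'other')}\n")
        fh.write("#edges\tbait\tprey\tscore\n")
        for a, b, data in sorted(net.edges(data=True)):
            fh.write(f"edge\t{a}\t{b}\t{data.get('score', float('nan')):.6g}\n")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image_tiff(image: MultiChannelImage, path,
                     scale_to_uint16: bool = True) -> None:
    """3-page 16-bit grayscale stack in channel order nuclei, pts1, pmp70."""
    pages = []
    for name in CHANNEL_NAMES:
        arr = image.channels[name]
        if scale_to_uint16:
            arr = np.clip(arr, 0, np.iinfo(np.uint16).max)
        pages.append(arr.astype(np.uint16))
    tifffile.imwrite(path, np.stack(pages), metadata={
        "axes": "CYX", "channels": ",".join(CHANNEL_NAMES),
        "pixel_size_um": image.pixel_size})


def read_image_tiff(path, pixel_size: float = 1.0) -> MultiChannelImage:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(CHANNEL_NAMES):
        raise ValueError(f"expected a {len(CHANNEL_NAMES)}-page stack, "
                         f"got shape {stack.shape}")
    channels = {name: stack[i].astype(float)
                for i, name in enumerate(CHANNEL_NAMES)}
    return MultiChannelImage(channels=channels, pixel_size=pixel_size)


def read_label_map_tiff(path) -> np.ndarray:
    """Externally produced integer label map (e.g. from another segmenter)."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError("label map must be a single 2-D page")
    return arr.astype(int)
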