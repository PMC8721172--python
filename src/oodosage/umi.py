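"""5' tag detection, UMI extraction and deduplicated UMI counting.

Tagged reads begin with the template-switching-oligo anchor
(AGATGTGTATAAGAGACAG by default), followed by a 12-nt UMI, fixed
post-UMI bases (ACG) and a stretch of template-switch G's; the cDNA
starts after the G-stretch. ``extract_tag`` locates this layout allowing
a bounded start offset and a bounded number of substitutions in the
anchor; ``count_umis`` deduplicates molecules by exact (gene, sample,
UMI) identity and produces the UMI count matrix.

Gene assignment is an input (a read_id -> gene table produced by the
synthetic generator or by any external aligner); no alignment happens
here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

import numpy as np
import pandas as pd

from .synthdata import TagPattern

_VALID = frozenset("ACGTN")


@dataclass
class TagMatch:
    umi: str
    cdna_start: int
    anchor_offset: int
    anchor_mismatches: int


def extract_tag(sequence: str, pattern: TagPattern | None = None) -> TagMatch | None:
    """Find the 5' tag in a read; return the UMI and cDNA offset, or None.

    The anchor may start at offsets 0..max_start_offset with at most
    ``allowed_mismatches_in_anchor`` substitutions (the lowest qualifying
    offset wins). It must be followed by exactly ``umi_length`` bases
    (no N), the exact post-UMI bases, and at least ``min_g_stretch``
    G's; the G-stretch is consumed greedily so cdna_start never points
    at a template-switch G.
    """
    pattern = pattern or TagPattern()
    if set(sequence) - _VALID:
        bad = sorted(set(sequence) - _VALID)
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    a = pattern.anchor
    la = len(a)
    for off in range(pattern.max_start_offset + 1):
        window = sequence[off:off + la]
        if len(window) < la:
            break
        mm = sum(1 for x, y in zip(window, a) if x != y)
        if mm > pattern.allowed_mismatches_in_anchor:
            continue
        p = off + la
        umi = sequence[p:p + pattern.umi_length]
        if len(umi) < pattern.umi_length or "N" in umi:
            continue
        p += pattern.umi_length
        post = sequence[p:p + len(pattern.post_umi)]
        if post != pattern.post_umi:
            continue
        p += len(pattern.post_umi)
        g = 0
        while p + g < len(sequence) and sequence[p + g] == "G":
            g += 1
        if g < pattern.min_g_stretch:
            continue
        return TagMatch(umi=umi, cdna_start=p + g, anchor_offset=off,
                        anchor_mismatches=mm)
    return None


def parse_fastq(handle: TextIO) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a 4-line-record FASTQ stream."""
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        handle.readline()  # quality
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError("malformed FASTQ record")
        yield header[1:].split()[0].rstrip("\n"), seq


def count_umis(
    reads: Iterable[tuple[str, str]],
    assignment: pd.DataFrame,
    samples: pd.DataFrame,
    pattern: TagPattern | None = None,
    features: Iterable[str] | None = None,
    collapse_hamming1: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Deduplicate tagged reads into a per-gene UMI count matrix.

    ``reads`` yields (read_id, sequence); ``assignment`` maps read_id to
    (sample_id, gene). count(g, s) is the number of distinct UMI strings
    among tag-matched reads assigned to gene g in sample s. Reads that
    fail tag extraction or lack a gene assignment are tallied in the QC
    report, not counted. Optional directional Hamming-1 collapse merges
    a UMI into a neighbour seen at >= 2x its read count (off by default).

    Returns (count matrix features x samples, QC report dict).
    """
    pattern = pattern or TagPattern()
    amap: dict[str, tuple[str, str]] = {}
    for r in assignment.itertuples(index=False):
        gene = getattr(r, "truth_gene", None)
        if gene is None:
            gene = r.gene
        if gene == "" or pd.isna(gene):
            continue
        amap[r.read_id] = (r.sample_id, gene)

    seen_ids: set[str] = set()
    # (sample, gene) -> {umi: read count}
    umis: dict[tuple[str, str], dict[str, int]] = {}
    qc = {"reads_in": 0, "tag_matched": 0, "assigned": 0,
          "unassigned": 0, "unmatched": 0}
    for rid, seq in reads:
        if rid in seen_ids:
            raise ValueError(f"duplicate read_id {rid}")
        seen_ids.add(rid)
        qc["reads_in"] += 1
        m = extract_tag(seq, pattern)
        if m is None:
            qc["unmatched"] += 1
            continue
        qc["tag_matched"] += 1
        hit = amap.get(rid)
        if hit is None:
            qc["unassigned"] += 1
            continue
        qc["assigned"] += 1
        key = hit
        umis.setdefault(key, {})
        umis[key][m.umi] = umis[key].get(m.umi, 0) + 1

    if collapse_hamming1:
        for key, table in umis.items():
            umis[key] = _directional_collapse(table)

    sample_ids = list(samples["sample_id"])
    if features is None:
        features = sorted({g for (_, g) in umis})
    features = list(features)
    mat = pd.DataFrame(0, index=pd.Index(features, name="feature_id"),
                       columns=sample_ids, dtype=np.int64)
    for (sample, gene), table in umis.items():
        if sample in mat.columns and gene in mat.index:
            mat.loc[gene, sample] = len(table)
    qc["distinct_umis"] = int(mat.to_numpy().sum())
    return mat, qc


def _directional_collapse(table: dict[str, int]) -> dict[str, int]:
    """Merge each UMI into a Hamming-1 neighbour with >= 2x its count."""
    order = sorted(table, key=lambda u: (-table[u], u))
    kept: dict[str, int] = {}
    for u in order:
        target = None
        for v in kept:
            if table[v] >= 2 * table[u] - 1 and _hamming(u, v) == 1:
                target = v
                break
        if target is None:
            kept[u] = table[u]
        else:
            kept[target] += table[u]
    return kept


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def write_qc_report(qc: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2)


def write_mtx(counts: pd.DataFrame, prefix: str) -> None:
    """MatrixMarket export: <prefix>.mtx plus feature/sample sidecars."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(counts.to_numpy()))
    with open(f"{prefix}.features.tsv", "w") as fh:
        fh.write("\n".join(counts.index) + "\n")
    with open(f"{prefix}.samples.tsv", "w") as fh:
        fh.write("\n".join(counts.columns) + "\n")
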