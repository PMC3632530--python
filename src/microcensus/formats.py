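"""Readers and writers for common OTU-clustering output formats.

Supported: BIOM v1 (JSON, dense and sparse), QIIME legacy tab-delimited
OTU tables with a lineage column, mothur ``.shared`` / ``.cons.taxonomy``
pairs, Newick trees, FASTA reference sequences, and TSV/CSV sample tables.
Every reader returns objects that pass :func:`microcensus.core.build_experiment`
validation.  An "experiment bundle" (zip of the per-component files) is the
canonical serialized form used by the CLI.
"""

from __future__ import annotations

import csv
import io
import json
import re
import zipfile
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AbundanceTable,
    Experiment,
    MISSING,
    PhyloTree,
    build_experiment,
    make_refseq,
    make_sample_table,
    make_taxonomy_table,
)


class FormatError(ValueError):
    """Raised for malformed or unsupported input files."""


# Greengenes-style rank prefixes, the dominant convention in QIIME-era files.
GREENGENES_PREFIXES = {
    "k__": "Kingdom", "p__": "Phylum", "c__": "Class", "o__": "Order",
    "f__": "Family", "g__": "Genus", "s__": "Species",
}
RANK_ORDER = list(GREENGENES_PREFIXES.values())

MISSING_TOKENS = {"", "na", "n/a"}  # case-insensitive

UNSUPPORTED_FORMATS = {
    "rdp": "RDP pipeline exports are not supported; export your data as BIOM v1 "
           "or a QIIME legacy OTU table instead",
    "pyrotagger": "Pyrotagger spreadsheets are not supported; export your data "
                  "as BIOM v1 or a QIIME legacy OTU table instead",
}


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon-delimited lineage into rank -> name.

    Greengenes prefixes (``k__`` ... ``s__``) map to their ranks; a prefix
    with an empty suffix is a missing value.  Unprefixed entries fill ranks
    positionally.  mothur-style bootstrap confidences ``(NN)`` are stripped.
    """
    out: dict[str, str] = {}
    parts = [p.strip() for p in lineage.split(";")]
    parts = [p for p in parts if p != ""] if lineage.strip().endswith(";") else parts
    pos = 0
    for part in parts:
        part = re.sub(r"\(\d+(\.\d+)?\)$", "", part).strip().strip('"')
        prefix = part[:3]
        if prefix in GREENGENES_PREFIXES:
            rank = GREENGENES_PREFIXES[prefix]
            name = part[3:].strip()
            out[rank] = name if name else MISSING
            pos = RANK_ORDER.index(rank) + 1
        else:
            if pos < len(RANK_ORDER):
                out[RANK_ORDER[pos]] = part if part else MISSING
                pos += 1
    return out


def _taxonomy_frame(lineages: Mapping[str, str]) -> pd.DataFrame | None:
    rows = {tid: parse_lineage(lin) for tid, lin in lineages.items()}
    if not any(rows.values()):
        return None
    ranks = [r for r in RANK_ORDER if any(r in v for v in rows.values())]
    frame = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=ranks)
    return make_taxonomy_table(frame, ranks)


# ---------------------------------------------------------------------------
# BIOM v1 JSON
# ---------------------------------------------------------------------------

def read_biom_json(path) -> Experiment:
    """Read a BIOM v1 JSON table (dense or sparse) into an Experiment.

    Observation metadata ``taxonomy`` lists populate the taxonomy table;
    sample metadata dicts populate the sample table.
    """
    raw = Path(path).read_bytes()
    if raw[:4] == b"\x89HDF":
        raise FormatError("this is a BIOM v2 (HDF5) file; only BIOM v1 JSON is "
                          "supported — convert with `biom convert --to-json`")
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid BIOM v1 JSON: {exc}") from exc

    shape = doc.get("shape")
    data = doc.get("data")
    mtype = doc.get("matrix_type")
    rows = doc.get("rows") or []
    cols = doc.get("columns") or []
    if shape is None or data is None or mtype is None:
        raise FormatError("BIOM file missing required keys (shape/data/matrix_type)")
    n_taxa, n_samples = int(shape[0]), int(shape[1])
    if len(rows) != n_taxa or len(cols) != n_samples:
        raise FormatError("BIOM rows/columns length does not match shape")

    mat = np.zeros((n_taxa, n_samples))
    if mtype == "dense":
        arr = np.asarray(data, dtype=float)
        if arr.shape != (n_taxa, n_samples):
            raise FormatError(f"dense data shape {arr.shape} != shape {tuple(shape)}")
        mat = arr
    elif mtype == "sparse":
        for triplet in data:
            i, j, v = int(triplet[0]), int(triplet[1]), float(triplet[2])
            if not (0 <= i < n_taxa and 0 <= j < n_samples):
                raise FormatError(f"sparse index ({i},{j}) outside shape {tuple(shape)}")
            mat[i, j] = v
    else:
        raise FormatError(f"unknown BIOM matrix_type {mtype!r} (expected dense|sparse)")

    taxon_ids = [str(r["id"]) for r in rows]
    sample_ids = [str(c["id"]) for c in cols]
    ab = AbundanceTable(mat, taxon_ids, sample_ids, taxa_are_rows=True)

    taxonomy = None
    lineages = {}
    for r in rows:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy")
        if tax:
            lineages[str(r["id"])] = ";".join(str(t) for t in tax)
    if lineages:
        taxonomy = _taxonomy_frame({tid: lineages.get(tid, "") for tid in taxon_ids})

    samples = None
    if any(c.get("metadata") for c in cols):
        recs = {str(c["id"]): (c.get("metadata") or {}) for c in cols}
        samples = _type_columns(pd.DataFrame.from_dict(recs, orient="index"))
        samples = make_sample_table(samples)

    return build_experiment(ab, samples=samples, taxonomy=taxonomy)


def write_biom_json(exp: Experiment, path) -> None:
    """Write the abundance (+taxonomy as observation metadata) as BIOM v1
    JSON with a dense matrix; round-trips through :func:`read_biom_json`."""
    rows = []
    for t in exp.taxon_ids:
        meta = None
        if exp.taxonomy is not None:
            assignment = [v for v in exp.taxonomy.loc[t].tolist()]
            prefixes = {v: k for k, v in GREENGENES_PREFIXES.items()}
            tax = [prefixes.get(rank, "") + ("" if val == MISSING else val)
                   for rank, val in zip(exp.taxonomy.columns, assignment)]
            meta = {"taxonomy": tax}
        rows.append({"id": t, "metadata": meta})
    cols = []
    for s in exp.sample_ids:
        meta = None
        if exp.samples is not None:
            meta = {k: (None if pd.isna(v) else v)
                    for k, v in exp.samples.loc[s].items()}
        cols.append({"id": s, "metadata": meta})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microcensus",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": [exp.n_taxa, exp.n_samples],
        "rows": rows,
        "columns": cols,
        "data": exp.abundance.values.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# QIIME legacy OTU table
# ---------------------------------------------------------------------------

def read_qiime_legacy(path) -> Experiment:
    """Read a QIIME legacy tab-delimited OTU table.

    The header line must begin with ``#OTU ID``; an optional final
    ``Consensus Lineage`` (or ``taxonomy``) column is parsed into a
    taxonomy table with greengenes prefix mapping.
    """
    lines = Path(path).read_text().splitlines()
    header = None
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#OTU ID"):
            header = line.split("\t")
            data_start = i + 1
            break
    if header is None:
        raise FormatError('not a QIIME legacy OTU table: no "#OTU ID" header line')

    lineage_col = None
    if header and header[-1].strip().lower() in {"consensus lineage", "taxonomy"}:
        lineage_col = len(header) - 1
    sample_ids = header[1:lineage_col if lineage_col else None]

    taxon_ids, counts, lineages = [], [], {}
    for line in lines[data_start:]:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        tid = fields[0]
        taxon_ids.append(tid)
        vals = fields[1:lineage_col if lineage_col else None]
        if len(vals) != len(sample_ids):
            raise FormatError(f"row {tid!r} has {len(vals)} values for "
                              f"{len(sample_ids)} samples")
        counts.append([float(v) for v in vals])
        if lineage_col is not None:
            lineages[tid] = fields[lineage_col]

    ab = AbundanceTable(np.array(counts), taxon_ids, sample_ids, taxa_are_rows=True)
    taxonomy = _taxonomy_frame(lineages) if lineages else None
    return build_experiment(ab, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# mothur
# ---------------------------------------------------------------------------

def read_mothur(shared_path, taxonomy_path=None, label: str | None = None) -> Experiment:
    """Read a mothur ``.shared`` file (and optional ``.cons.taxonomy``).

    ``.shared`` columns: label, Group, numOtus, then one count column per
    OTU.  When several distance labels are present one must be selected via
    ``label``.  Consensus-taxonomy bootstrap suffixes ``(NN)`` are stripped.
    """
    rows = [r for r in csv.reader(Path(shared_path).read_text().splitlines(),
                                  delimiter="\t") if r]
    header = rows[0]
    if [h.lower() for h in header[:3]] != ["label", "group", "numotus"]:
        raise FormatError(".shared file must start with columns label, Group, numOtus")
    otu_ids = header[3:]
    body = rows[1:]
    labels = sorted({r[0] for r in body})
    if label is None:
        if len(labels) > 1:
            raise FormatError(f"multiple distance labels present {labels}; "
                              f"select one with label=")
        label = labels[0]
    body = [r for r in body if r[0] == label]
    if not body:
        raise FormatError(f"label {label!r} not found; available: {labels}")

    sample_ids = [r[1] for r in body]
    counts = np.array([[float(v) for v in r[3:]] for r in body])  # samples x taxa
    ab = AbundanceTable(counts.T, otu_ids, sample_ids, taxa_are_rows=True)

    taxonomy = None
    if taxonomy_path is not None:
        trows = [r for r in csv.reader(Path(taxonomy_path).read_text().splitlines(),
                                       delimiter="\t") if r]
        theader = [h.lower() for h in trows[0]]
        if "otu" not in theader or "taxonomy" not in theader:
            raise FormatError(".cons.taxonomy needs OTU and Taxonomy columns")
        io_, it = theader.index("otu"), theader.index("taxonomy")
        lineages = {r[io_]: r[it] for r in trows[1:]}
        taxonomy = _taxonomy_frame(lineages)
    return build_experiment(ab, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# Newick / FASTA / sample tables
# ---------------------------------------------------------------------------

def read_newick(path_or_string) -> PhyloTree:
    """Read a Newick tree; unbalanced parentheses raise with a position."""
    text = str(path_or_string)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    stack = []
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(
                    f"unbalanced parentheses in newick: ')' at position {pos} "
                    "has no opening '('")
            stack.pop()
    if stack:
        raise FormatError(f"unbalanced parentheses in newick: '(' at "
                          f"position {stack[-1]} is never closed")
    tree = PhyloTree.from_newick(text)
    if tree.is_unrooted:
        from .core import logger
        logger.info("newick tree has a basal multifurcation; flagged unrooted")
    return tree


def read_fasta(path) -> dict[str, str]:
    """Read reference sequences (taxon id = first word of the header)."""
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            if current in seqs:
                raise FormatError(f"duplicate FASTA id {current!r}")
            seqs[current] = []
        elif current is not None and line.strip():
            seqs[current].append(line.strip())
    return make_refseq({k: "".join(v) for k, v in seqs.items()})


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for k, v in seqs.items():
            fh.write(f">{k}\n{v}\n")


def _type_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Type each column numeric when every non-missing value parses as a
    number, else categorical (string); missing tokens become NaN."""
    out = {}
    for col in frame.columns:
        vals = frame[col]
        parsed = []
        numeric = True
        for v in vals:
            sv = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
            if sv.lower() in MISSING_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(sv))
            except ValueError:
                numeric = False
                break
        if numeric:
            out[col] = pd.Series(parsed, index=frame.index, dtype=float)
        else:
            cleaned = [np.nan if str(v).strip().lower() in MISSING_TOKENS or v is None
                       else str(v).strip() for v in vals]
            out[col] = pd.Series(cleaned, index=frame.index, dtype=object)
    return pd.DataFrame(out, index=frame.index)


def read_sample_table(path) -> pd.DataFrame:
    """Read a TSV/CSV sample table (first column = sample IDs)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                        keep_default_na=False)
    frame.index = [str(i).strip() for i in frame.index]
    return make_sample_table(_type_columns(frame))


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="#SampleID")


def write_taxonomy_table(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="#TaxonID")


def read_taxonomy_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        keep_default_na=False)
    return make_taxonomy_table(frame)


# ---------------------------------------------------------------------------
# Experiment bundle (zip)
# ---------------------------------------------------------------------------

BUNDLE_MEMBERS = {
    "abundance": "otu_table.biom",
    "samples": "sample_data.tsv",
    "taxonomy": "taxonomy.tsv",
    "tree": "tree.nwk",
    "refseq": "refseq.fasta",
}


def write_bundle(exp: Experiment, path) -> None:
    """Serialize an Experiment as a zip bundle; absent components omitted."""
    import tempfile

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        with tempfile.TemporaryDirectory() as td:
            biom = Path(td) / "otu_table.biom"
            # taxonomy is embedded in the biom AND kept as tsv for readability
            write_biom_json(Experiment(exp.abundance), biom)
            zf.write(biom, BUNDLE_MEMBERS["abundance"])
        if exp.samples is not None:
            buf = io.StringIO()
            exp.samples.to_csv(buf, sep="\t", index_label="#SampleID")
            zf.writestr(BUNDLE_MEMBERS["samples"], buf.getvalue())
        if exp.taxonomy is not None:
            buf = io.StringIO()
            exp.taxonomy.to_csv(buf, sep="\t", index_label="#TaxonID")
            zf.writestr(BUNDLE_MEMBERS["taxonomy"], buf.getvalue())
        if exp.tree is not None:
            zf.writestr(BUNDLE_MEMBERS["tree"], exp.tree.to_newick() + "\n")
        if exp.refseq is not None:
            zf.writestr(BUNDLE_MEMBERS["refseq"], "".join(
                f">{k}\n{v}\n" for k, v in exp.refseq.items()))


def read_bundle(path) -> Experiment:
    """Read an experiment bundle written by :func:`write_bundle`."""
    import tempfile

    with zipfile.ZipFile(path) as zf, tempfile.TemporaryDirectory() as td:
        td = Path(td)
        zf.extractall(td)
        base = read_biom_json(td / BUNDLE_MEMBERS["abundance"])
        samples = taxonomy = tree = refseq = None
        if (td / BUNDLE_MEMBERS["samples"]).exists():
            samples = read_sample_table(td / BUNDLE_MEMBERS["samples"])
        if (td / BUNDLE_MEMBERS["taxonomy"]).exists():
            taxonomy = read_taxonomy_table(td / BUNDLE_MEMBERS["taxonomy"])
        if (td / BUNDLE_MEMBERS["tree"]).exists():
            tree = read_newick((td / BUNDLE_MEMBERS["tree"]).read_text())
        if (td / BUNDLE_MEMBERS["refseq"]).exists():
            refseq = read_fasta(td / BUNDLE_MEMBERS["refseq"])
        return build_experiment(base.abundance, samples=samples,
                                taxonomy=taxonomy, tree=tree, refseq=refseq)
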