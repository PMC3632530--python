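"""Optional external datasets.

The Arumugam et al. "Enterotypes" genus table (relative abundances of 553
genera across 280 gut metagenome samples, with the published enterotype
cluster labels) is not distributed with this package.  It ships with the
Bioconductor ``phyloseq`` R package; when an R installation with that
package is available, :func:`load_enterotype` exports it on the fly.
Alternatively point ``load_enterotype`` at a pre-exported directory
containing ``enterotype_otu.tsv`` and ``enterotype_samples.tsv``.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import pandas as pd

from .core import AbundanceTable, Experiment, build_experiment, make_sample_table

_R_EXPORT = r"""
suppressMessages(library(phyloseq))
data(enterotype)
x <- as(otu_table(enterotype), "matrix")
sd <- data.frame(sample_data(enterotype))
write.table(x, file.path("{dest}", "enterotype_otu.tsv"),
            sep = "\t", quote = FALSE, col.names = NA)
write.table(data.frame(SampleID = rownames(sd), Enterotype = as.character(sd$Enterotype)),
            file.path("{dest}", "enterotype_samples.tsv"),
            sep = "\t", quote = FALSE, row.names = FALSE)
"""


def enterotype_available() -> bool:
    """True when Rscript + the phyloseq data package can serve the table."""
    try:
        proc = subprocess.run(
            ["Rscript", "-e", "suppressMessages(library(phyloseq)); data(enterotype); cat(1)"],
            capture_output=True, timeout=120)
        return proc.returncode == 0 and b"1" in proc.stdout
    except (OSError, subprocess.TimeoutExpired):
        return False


def load_enterotype(path: str | Path | None = None) -> Experiment:
    """The Enterotypes genus x sample experiment.

    ``path``: directory with pre-exported ``enterotype_otu.tsv`` /
    ``enterotype_samples.tsv``; when omitted the table is exported from
    the R phyloseq package into a temporary directory.  Samples the
    original authors did not assign to an enterotype carry a missing
    Enterotype value (drop them with :func:`microcensus.prune_samples`).
    """
    if path is None:
        with tempfile.TemporaryDirectory() as td:
            script = _R_EXPORT.replace("{dest}", td)
            proc = subprocess.run(["Rscript", "-e", script],
                                  capture_output=True, timeout=300)
            if proc.returncode != 0:
                raise RuntimeError(
                    "could not export the enterotype dataset via Rscript "
                    "(is R with the Bioconductor phyloseq package installed?): "
                    + proc.stderr.decode(errors="replace")[-500:])
            return load_enterotype(td)
    path = Path(path)
    otu = pd.read_csv(path / "enterotype_otu.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(path / "enterotype_samples.tsv", sep="\t",
                          index_col=0, dtype=str)
    ab = AbundanceTable(otu.values, [str(i) for i in otu.index],
                        [str(c) for c in otu.columns])
    return build_experiment(ab, samples=make_sample_table(samples))
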