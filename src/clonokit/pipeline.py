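"""End-to-end repertoire run: combine -> metrics -> diversity -> join.

The pipeline is a thin orchestration over the library operations — it adds
no computation of its own, only file layout and a run manifest. It is
driven by a declarative config (a YAML file for the CLI, a plain dict for
library use):

.. code-block:: yaml

    mode: TCR            # or BCR
    call_by: aa          # gene | nt | aa | strict
    dialect: tenx_csv    # or airr_tsv
    seed: 1
    samples:
      - {name: P1, group: peripheral, contigs: P1.csv, metadata: P1.meta.tsv}
      - {name: T1, group: tumor, contigs: T1.csv}
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .combine import combine_receptors, count_clonotypes
from .contigs import FilterSpec, filter_contigs, read_contigs
from .diversity import clone_size_jsd, diversity_table, overlap_matrix
from .expression import FrequencyBins, combine_expression
from .metrics import (
    HomeostasisBins,
    abundance_table,
    cdr3_lengths,
    clonal_homeostasis,
    clonal_proportion,
    export_table,
    quantify_unique,
)


def validate_config(config: dict) -> dict:
    """Check the run config and resolve paths before any computation."""
    cfg = dict(config)
    samples = cfg.get("samples")
    if not samples:
        raise ValueError("config must list at least one sample")
    names = [s["name"] for s in samples]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names in config")
    for s in samples:
        path = Path(s["contigs"])
        if not path.exists():
            raise FileNotFoundError(f"sample {s['name']}: contig file "
                                    f"not found: {path}")
        if "metadata" in s and not Path(s["metadata"]).exists():
            raise FileNotFoundError(f"sample {s['name']}: metadata file "
                                    f"not found: {s['metadata']}")
    cfg.setdefault("mode", "TCR")
    cfg.setdefault("call_by", "aa")
    cfg.setdefault("dialect", "tenx_csv")
    cfg.setdefault("seed", 0)
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full analysis described by ``config`` into ``outdir``.

    Writes per-sample clonotype tables, quantification / abundance / CDR3
    length tables, homeostasis and clonal-proportion tables, the diversity
    table, both overlap matrices, the clone-size JSD matrix and dendrogram,
    joined metadata when supplied, and a JSON run manifest. Returns the
    manifest dict.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "clonokit",
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "outputs": [],
        "complete": False,
    }

    def emit(result, name):
        path = outdir / name
        export_table(result, path)
        manifest["outputs"].append(name)

    try:
        mode, call_by = cfg["mode"], cfg["call_by"]
        fspec = FilterSpec.default(mode)
        tables, names, groups = [], [], []
        has_groups = any("group" in s for s in cfg["samples"])
        for s in cfg["samples"]:
            raw = read_contigs(s["contigs"], dialect=cfg["dialect"])
            tables.append(filter_contigs(raw, fspec))
            names.append(s["name"])
            groups.append(s.get("group"))
        rep = combine_receptors(tables, names,
                                group_names=groups if has_groups else None,
                                mode=mode)
        rep.save(outdir / "clonotypes")
        manifest["outputs"].append("clonotypes/")

        counts = count_clonotypes(rep, call_by=call_by)
        quant_rows = []
        for name, cv in counts.items():
            unique, scaled = quantify_unique(cv, scaled=True)
            quant_rows.append({"sample": name, "cells": cv.total,
                               "unique": unique, "scaled_pct": scaled})
            emit(abundance_table(cv), f"abundance.{name}.tsv")
            emit(clonal_homeostasis(cv, HomeostasisBins()),
                 f"homeostasis.{name}.tsv")
            emit(clonal_proportion(cv), f"clonal_proportion.{name}.tsv")
        emit(pd.DataFrame(quant_rows), "quantification.tsv")
        emit(cdr3_lengths(rep, call_by="nt"), "cdr3_lengths.tsv")
        emit(diversity_table(counts), "diversity.tsv")

        if len(counts) >= 2:
            for method in ("morisita", "overlap_coefficient"):
                mat = overlap_matrix(counts, method=method)
                path = outdir / f"overlap.{method}.tsv"
                mat.to_csv(path, sep="\t")
                manifest["outputs"].append(path.name)
            clust = clone_size_jsd(counts)
            clust.distance.to_csv(outdir / "jsd.matrix.tsv", sep="\t")
            (outdir / "jsd.dendrogram.nwk").write_text(clust.to_newick()
                                                       + "\n")
            manifest["outputs"] += ["jsd.matrix.tsv", "jsd.dendrogram.nwk"]

        meta_paths = [s["metadata"] for s in cfg["samples"]
                      if "metadata" in s]
        if meta_paths:
            meta = pd.concat([pd.read_csv(p, sep="\t") for p in meta_paths],
                             ignore_index=True)
            joined = combine_expression(rep, meta, call_by=call_by,
                                        bins=FrequencyBins())
            emit(joined, "metadata_joined.tsv")
        manifest["complete"] = True
    finally:
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n")
    return manifest
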