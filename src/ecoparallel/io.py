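"""Readers and writers for the five study tables.

Genotypes travel as VCF 4.2 (GT field only, missing "./.") or as a
dosage TSV; samples/traits/environment as CSV; counts and gene positions
as TSV; the truth record as JSON; configs as YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .popgen import GenotypeDataset
from .synth import StudyBundle, SynthConfig

logger = logging.getLogger(__name__)

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Minimal biallelic VCF with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.sample_ids) + "\n")
        for j, row in enumerate(dataset.loci.itertuples()):
            gts = [_GT.get(d, "./.") if np.isfinite(d) else "./."
                   for d in dataset.dosages[:, j]]
            fh.write(f"{row.chrom}\t{row.pos}\tsnp{j + 1}\tA\tT\t.\tPASS\t"
                     f"CTG={row.contig}\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path) -> GenotypeDataset:
    """Read a VCF (GT field only) into a dosage matrix plus locus table.

    Multi-allelic records are skipped (count logged); "./." becomes
    missing; 1-based positions are preserved.
    """
    samples: list[str] = []
    loci_rows = []
    dosage_rows = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, _, ref, alt = fields[:5]
            if "," in alt:
                skipped += 1
                continue
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            contig = ""
            for kv in fields[7].split(";"):
                if kv.startswith("CTG="):
                    contig = kv[4:]
            dos = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(int(a) for a in gt.split("/"))))
            loci_rows.append({"chrom": chrom, "pos": int(pos),
                              "contig": contig or f"{chrom}:{pos}"})
            dosage_rows.append(dos)
    if skipped:
        logger.info("skipped %d multi-allelic records", skipped)
    loci = pd.DataFrame(loci_rows)
    dosages = np.asarray(dosage_rows, dtype=float).T if dosage_rows else np.empty((len(samples), 0))
    return GenotypeDataset(dosages=dosages, loci=loci, sample_ids=samples)


def write_dosage_tsv(dataset: GenotypeDataset, path) -> None:
    df = pd.DataFrame(dataset.dosages.T, columns=dataset.sample_ids)
    out = pd.concat([dataset.loci.reset_index(drop=True), df], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    meta_cols = [c for c in ("chrom", "pos", "contig", "assoc") if c in df.columns]
    loci = df[meta_cols]
    dosages = df.drop(columns=meta_cols).to_numpy(dtype=float).T
    return GenotypeDataset(dosages=dosages, loci=loci,
                           sample_ids=[c for c in df.columns if c not in meta_cols])


def write_bundle(bundle: StudyBundle, outdir) -> dict:
    """Write all five tables (plus truth) under ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.csv",
        "traits": outdir / "traits.csv",
        "environment": outdir / "environment.csv",
        "counts": outdir / "counts.tsv",
        "genes": outdir / "genes.tsv",
        "vcf": outdir / "genotypes.vcf",
        "dosages": outdir / "genotypes.tsv",
        "truth": outdir / "truth.json",
    }
    bundle.samples.to_csv(paths["samples"], index=False)
    bundle.traits.to_csv(paths["traits"])
    bundle.environment.to_csv(paths["environment"], index=False)
    bundle.counts.to_csv(paths["counts"], sep="\t")
    bundle.genes.to_csv(paths["genes"], sep="\t", index=False)
    gd = GenotypeDataset(bundle.genotypes, bundle.loci,
                         list(bundle.samples["id"]))
    write_vcf(gd, paths["vcf"])
    write_dosage_tsv(gd, paths["dosages"])
    with open(paths["truth"], "w") as fh:
        json.dump(_jsonable(bundle.truth), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path) -> SynthConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "allometry_slopes" in raw and raw["allometry_slopes"] is not None:
        raw["allometry_slopes"] = tuple(raw["allometry_slopes"])
    return SynthConfig(**raw)


def save_config(config: SynthConfig, path) -> None:
    import dataclasses
    d = dataclasses.asdict(config)
    if d.get("allometry_slopes") is not None:
        d["allometry_slopes"] = list(d["allometry_slopes"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
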