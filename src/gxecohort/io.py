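"""Readers and writers for the pipeline's external file formats.

Everything round-trips through tidy CSV: dosage matrices (subjects x loci
with a header row of locus ids), diet/subject/census tables, retail panels,
and smoothed exposures keyed by FSA.  A minimal VCF path exists for dosage
matrices: the writer emits a sites x samples VCF with a ``DS`` FORMAT
field (synthetic stand-in loci — positions are placeholders, the dosages
are the payload); reading uses :mod:`pysam` when available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def write_dosage_csv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, index_label="subject")


def read_dosage_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject")
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | ((vals >= 0) & (vals <= 2))
    if not ok.all():
        raise ValueError("dosages outside [0, 2] in dosage CSV")
    return df


def write_dosage_vcf(genotypes: pd.DataFrame, path) -> None:
    """Write a minimal VCF v4.2 with a DS (dosage) FORMAT field.

    Loci get synthetic placeholder coordinates (chr1, consecutive
    positions); only the DS values carry information.
    """
    path = Path(path)
    samples = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in samples) + "\n")
        for j, locus in enumerate(genotypes.columns, start=1):
            ds = genotypes[locus].to_numpy(dtype=float)
            cells = "\t".join("." if np.isnan(d) else f"{d:g}" for d in ds)
            fh.write(f"1\t{j * 1000}\t{locus}\tA\tG\t.\tPASS\t.\tDS\t{cells}\n")


def read_dosage_vcf(path) -> pd.DataFrame:
    """Read a DS-field VCF into a subjects x loci dosage matrix."""
    from pysam import VariantFile

    loci, rows = [], []
    with VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            loci.append(rec.id)
            rows.append([
                np.nan if rec.samples[s].get("DS") is None
                else float(rec.samples[s]["DS"])
                for s in samples
            ])
    return pd.DataFrame(np.asarray(rows).T, index=samples, columns=loci)


def write_study(study, out_dir) -> dict:
    """Write every table of a synthetic study as tidy CSV + truth ledger."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_dosage_csv(study.genotypes, out / "genotypes.csv")
    paths["genotypes"] = str(out / "genotypes.csv")
    for name in ("diet", "retail", "census", "subjects"):
        df = getattr(study, name)
        df.to_csv(out / f"{name}.csv",
                  index=(name in ("diet", "subjects")),
                  index_label="subject" if name in ("diet", "subjects") else None)
        paths[name] = str(out / f"{name}.csv")
    if study.exposures is not None:
        study.exposures.to_csv(out / "exposures.csv")
        paths["exposures"] = str(out / "exposures.csv")
    truth = {k: (dict(v) if hasattr(v, "items") else v)
             for k, v in study.truth.items()}
    truth = {k: ({kk: (dict(vv) if hasattr(vv, "items") else vv)
                  for kk, vv in v.items()} if isinstance(v, dict) else v)
             for k, v in truth.items()}
    (out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    paths["truth"] = str(out / "truth.yaml")
    return paths
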