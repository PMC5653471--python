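"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as phased VCF (uncompressed, `|`-separated GT);
pedigree, phenotypes, origins and relationship matrices as TSV.  Every
file written here carries the run seed in a header comment.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .boa import OriginMatrix
from .grm import GenomicMatrix
from .simdata import HaplotypePanel, ORIGIN_NAMES, UNASSIGNED


def write_vcf(panel: HaplotypePanel, path: str, seed: int = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=crossblup\n")
        if seed is not None:
            fh.write(f"##crossblup_seed={seed}\n")
        for c in np.unique(panel.chrom):
            n = int((panel.chrom == c).sum())
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in panel.ids) + "\n")
        pos_in_chrom = {}
        for j in range(panel.n_loci):
            c = panel.chrom[j]
            pos_in_chrom[c] = pos_in_chrom.get(c, 0) + 1
            gts = "\t".join(f"{panel.haplo[k, j, 0]}|{panel.haplo[k, j, 1]}"
                            for k in range(panel.n_ind))
            fh.write(f"{c}\t{pos_in_chrom[c]}\tsnp{j}\tA\tB\t.\tPASS\t"
                     f"GP={panel.pos[j]:.6f}\tGT\t{gts}\n")


def read_vcf(path: str, breeds: dict = None) -> HaplotypePanel:
    """Read a phased VCF into a panel (requires `|`-phased genotypes)."""
    from cyvcf2 import VCF
    vcf = VCF(path)
    ids = list(vcf.samples)
    chrom, pos, rows = [], [], []
    for var in vcf:
        chrom.append(int(var.CHROM))
        gp = var.INFO.get("GP")
        pos.append(float(gp) if gp is not None else float(var.POS))
        g = np.array(var.genotypes)  # (n_samples, [allele1, allele2, phased])
        if not g[:, 2].all():
            raise ValueError("unphased genotypes; phase upstream")
        rows.append(g[:, :2].astype(np.int8))
    hap = np.stack(rows, axis=1)  # (n_ind, n_loci, 2)
    breeds_arr = np.array([(breeds or {}).get(i, "NA") for i in ids],
                          dtype=object)
    return HaplotypePanel(ids, breeds_arr, np.asarray(chrom),
                          np.asarray(pos), hap)


def write_pedigree(pedigree: pd.DataFrame, path: str, seed: int = None):
    _write_tsv(pedigree, path, seed)


def read_pedigree(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"id": str, "sire": str, "dam": str})


def write_phenotypes(phenos: pd.DataFrame, path: str, seed: int = None):
    _write_tsv(phenos, path, seed)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})


def _write_tsv(df: pd.DataFrame, path: str, seed=None):
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# crossblup_seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _rle(codes) -> str:
    out, prev, run = [], None, 0
    for c in codes:
        if c == prev:
            run += 1
        else:
            if prev is not None:
                out.append(f"{prev}:{run}")
            prev, run = c, 1
    out.append(f"{prev}:{run}")
    return ",".join(out)


def _unrle(text: str):
    vals = []
    for tok in text.split(","):
        c, n = tok.split(":")
        vals.extend([c] * int(n))
    return vals


def write_origins(origins: OriginMatrix, panel: HaplotypePanel, path: str,
                  seed: int = None) -> None:
    """One row per CB individual x gamete, RLE label string per chromosome."""
    code2lab = dict(ORIGIN_NAMES)
    code2lab[UNASSIGNED] = "U"
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# crossblup_seed={seed}\n")
        fh.write("id\tgamete\tchrom\tlabels_rle\n")
        for i in origins.ids:
            k = origins.row(i)
            for g, gname in enumerate(("paternal", "maternal")):
                for c, lo, hi in panel.chromosome_slices():
                    labs = [code2lab[int(v)] for v in origins.codes[k, lo:hi, g]]
                    fh.write(f"{i}\t{gname}\t{c}\t{_rle(labs)}\n")


def read_origins(path: str, panel: HaplotypePanel) -> OriginMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    ids = list(dict.fromkeys(df["id"]))
    lab2code = {**{v: k for k, v in ORIGIN_NAMES.items()}, "U": UNASSIGNED}
    codes = np.full((len(ids), panel.n_loci, 2), UNASSIGNED, dtype=np.int8)
    idx = {i: k for k, i in enumerate(ids)}
    slices = {c: (lo, hi) for c, lo, hi in panel.chromosome_slices()}
    for _, row in df.iterrows():
        lo, hi = slices[row["chrom"]]
        g = 0 if row["gamete"] == "paternal" else 1
        vals = [lab2code[v] for v in _unrle(row["labels_rle"])]
        codes[idx[row["id"]], lo:hi, g] = vals
    return OriginMatrix(ids, codes)


def write_grm(G: GenomicMatrix, path: str, seed: int = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# crossblup_seed={seed} flavor={G.flavor}\n")
        G.to_frame().to_csv(fh, sep="\t")


def read_grm(path: str, flavor: str = "unknown") -> GenomicMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return GenomicMatrix(list(df.index), df.to_numpy(dtype=float), flavor)


def write_config_echo(config, path: str) -> None:
    from dataclasses import asdict
    with open(path, "w") as fh:
        fh.write(f"# crossblup_seed={config.seed}\n")
        for k, v in asdict(config).items():
            fh.write(f"{k}={v}\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
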