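"""Readers for phenotype and genotype tables (plain delimited text)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mme import RecordSet
from .pedigree import Pedigree

__all__ = ["read_phenotypes", "read_genotypes", "build_records"]


def _read(path):
    return pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                       comment="#", skip_blank_lines=True)


def read_phenotypes(path, ped: Pedigree) -> np.ndarray:
    """Read ``animal value`` rows; returns a y vector with NaN elsewhere."""
    df = _read(path)
    y = np.full(ped.n, np.nan)
    idx = ped.indices_of(df.iloc[:, 0].tolist())
    y[idx] = df.iloc[:, 1].astype(float).to_numpy()
    return y


def _parse_genotype(tok: str):
    """A genotype token -> list of alleles.

    Accepts gene content (``0``/``1``/``2``, meaning copies of the B
    allele), slash-separated alleles (``A/B``, ``1/3``) or a two-letter
    pair (``AB``).
    """
    tok = tok.strip()
    if tok in ("0", "1", "2"):
        k = int(tok)
        return ["A"] * (2 - k) + ["B"] * k
    if "/" in tok:
        alleles = tok.split("/")
    else:
        alleles = list(tok)
    if len(alleles) != 2:
        raise ValueError(f"cannot parse genotype {tok!r}")
    return alleles


def read_genotypes(path, ped: Pedigree, reference: str | None = None):
    """Read ``animal genotype`` rows into per-allele gene contents.

    Returns ``(z, alleles)``: for a biallelic gene, ``z`` is (n, 1)
    counts of the reference allele (default: the lexicographically last
    allele, so ``A``/``B`` coding counts B); for k > 2 alleles, ``z``
    is (n, k-1) with the last (reference) allele dropped.
    """
    df = _read(path)
    idx = ped.indices_of(df.iloc[:, 0].tolist())
    pairs = [_parse_genotype(t) for t in df.iloc[:, 1]]
    alleles = sorted({a for p in pairs for a in p})
    if len(alleles) < 2:
        alleles = sorted(set(alleles) | {"A", "B"})
    if reference is None:
        reference = alleles[-1]
    if reference not in alleles:
        raise ValueError(f"reference allele {reference!r} not observed")
    if len(alleles) == 2:
        kept = [reference]
    else:
        kept = [a for a in alleles if a != reference]
    z = np.full((ped.n, len(kept)), np.nan)
    for i, pair in zip(idx, pairs):
        z[i] = [pair.count(a) for a in kept]
    return z, alleles


def build_records(ped: Pedigree, phenotype_path=None, genotype_path=None,
                  reference=None) -> RecordSet:
    """Assemble a :class:`RecordSet` from phenotype/genotype files."""
    y = (read_phenotypes(phenotype_path, ped) if phenotype_path
         else np.full(ped.n, np.nan))
    if genotype_path:
        z, _ = read_genotypes(genotype_path, ped, reference)
    else:
        z = np.full((ped.n, 1), np.nan)
    return RecordSet(y=y, z=z)
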