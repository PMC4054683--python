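"""Shared fixtures: the standard planted dataset and small toy objects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import transppi as tp


@pytest.fixture(scope="session")
def planted():
    """The standard planted study (seed 1), simulated once per session."""
    return tp.standard_planted_dataset(seed=1)


@pytest.fixture(scope="session")
def planted_filtered(planted):
    """QC-filtered genotypes with sample-aligned expression."""
    geno = tp.filter_genotypes(planted.genotypes)
    expr = planted.expression.align_samples(geno.samples)
    return geno, expr


@pytest.fixture(scope="session")
def exon_scan(planted, planted_filtered):
    """Exon-region trans scans at the strict and candidate thresholds."""
    geno, expr = planted_filtered
    strict = tp.scan_trans(geno, expr, planted.annotation, "exonic", 1e-6)
    candidates = tp.scan_trans(geno, expr, planted.annotation, "exonic", 1e-3)
    return strict, candidates


def make_genotypes(dosage_rows, chrom="chr1", start_pos=100,
                   source_gene="", exonic=True, tf_span=False):
    """Build a GenotypeMatrix from a list of per-sample dosage rows."""
    dosages = np.asarray(dosage_rows, dtype=np.int8)
    n_samples, n_snps = dosages.shape
    meta = pd.DataFrame({
        "chromosome": [chrom] * n_snps,
        "position": [start_pos + j for j in range(n_snps)],
        "source_gene": [source_gene] * n_snps,
        "exonic": [exonic] * n_snps,
        "tf_span": [tf_span] * n_snps,
    }, index=pd.Index([f"snp{j + 1}" for j in range(n_snps)], name="snp_id"))
    return tp.GenotypeMatrix(
        samples=[f"S{i + 1}" for i in range(n_samples)],
        dosages=dosages, snp_meta=meta)
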