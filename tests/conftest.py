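"""Shared fixtures: published summary inputs and an independent naive matcher.

The 15 SNP flanking contexts, the rs9395890 genotype counts and the qPCR
group summaries are published summary data used as *inputs*; everything the
pipeline is supposed to compute from them is recomputed in the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from regsnp_screen.motif_scan import NFKB_CONSENSUS, reverse_complement

# (snp id, call rate, MAF, context LEFT[REF/ALT]RIGHT) — flanks are ±9 bp
TABLE1_CONTEXTS = [
    ("rs17036427", 1.000, 0.0807, "AAAGGCAGG[G/C]ATTTTCCCC"),
    ("rs79143300", 0.997, 0.0820, "CAATGTGGC[G/T]GGAATTTCC"),
    ("rs76552560", 0.995, 0.1346, "AAGTCCCCC[G/A]GGAAGTCCC"),
    ("rs7651075", 0.997, 0.4940, "CCGTGGGTT[G/A]GGAAACTCC"),
    ("rs59118205", 0.997, 0.0594, "GGGGTTTCC[C/T]CACCATGAT"),
    ("rs9395890", 0.999, 0.4157, "GTGACAGCT[T/G]GGAAGTCCC"),
    ("rs11826681", 0.916, 0.4157, "CGTGAGGGG[C/G]ATTTCCAGC"),
    ("rs11234413", 1.000, 0.0973, "CATCACCAG[G/A]GGAATCTCC"),
    ("rs2851583", 0.999, 0.0572, "TTCTGAAGG[A/G]AAGTCCCTC"),
    ("rs9925427", 0.993, 0.1258, "GCAGCGCCC[A/G]GGACTTTCC"),
    ("rs78229468", 0.955, 0.0861, "TGCTGCTGG[A/G]AAGTTCCTG"),
    ("rs77836284", 0.999, 0.0858, "GGGGATTTC[C/T]CGCTCGGCT"),
    ("rs3826454", 0.998, 0.1050, "CCCTTGGGG[A/T]ATTTCCTCA"),
    ("rs67087171", 1.000, 0.1153, "TAGAAGGGC[G/A]GGATTTCCC"),
    ("rs7284245", 0.997, 0.1650, "CTTGGGCCG[G/T]GGACTTCCC"),
]

# rs9395890 genotype counts, (GG, GT, TT) with T the risk allele
RS9395890_CONTROL = (153, 419, 274)
RS9395890_CASE = (138, 379, 324)

# qPCR percent-input group summaries (mean, SEM), n = 3 per genotype
QPCR_GROUP_MEANS = {"GG": 1.71, "GT": 2.81, "TT": 3.20}
QPCR_GROUP_SEMS = {"GG": 0.18, "GT": 0.20, "TT": 0.16}


def parse_context(ctx: str) -> tuple[str, str, str, str]:
    """Split LEFT[REF/ALT]RIGHT into (left, ref, alt, right)."""
    left, rest = ctx.split("[")
    alleles, right = rest.split("]")
    ref, alt = alleles.split("/")
    return left, ref, alt, right


def naive_scan(seq: str, consensus: str = NFKB_CONSENSUS) -> list[tuple[int, str]]:
    """Brute-force double-loop matcher over every offset and strand.

    Independent oracle for scan(): no regex, no shared code path.
    """
    sets = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "N": "ACGTN",
    }
    out = []
    L = len(consensus)
    rc = reverse_complement(consensus)
    for start in range(len(seq) - L + 1):
        sub = seq[start : start + L]
        if all(sub[i] in sets[consensus[i]] for i in range(L)):
            out.append((start, "+"))
        if all(sub[i] in sets[rc[i]] for i in range(L)):
            out.append((start, "-"))
    return sorted(out)


@pytest.fixture(scope="session")
def dataset():
    """One fully generated synthetic study, shared across tests."""
    from regsnp_screen.synthetic_data import SimulationConfig, generate_dataset

    return generate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def dataset_paths(dataset, tmp_path_factory):
    return dataset.write(tmp_path_factory.mktemp("synthetic"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
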