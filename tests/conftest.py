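"""Shared fixtures: a small deterministic synthetic cohort and a hand-written
micro VCF used by the parsing tests."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from iqgene.pipeline import CohortData, load_cohort
from iqgene.simulate import SimulatedCohort, SimulationConfig, simulate_cohort

#: seed and scale of the shared fixture cohort; small enough that the whole
#: suite reruns it in seconds, large enough to exercise every category
FIXTURE_SEED = 20260926
FIXTURE_CONFIG = dict(n_patients=20, n_genes=80, n_driver_genes=2, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory) -> SimulatedCohort:
    out = tmp_path_factory.mktemp("sim_cohort")
    return simulate_cohort(SimulationConfig(**FIXTURE_CONFIG), out)


@pytest.fixture(scope="session")
def ingested(sim_cohort) -> CohortData:
    return load_cohort(sim_cohort.manifest_path)


MICRO_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1>
    ##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: Allele|Consequence|SYMBOL|Feature|BIOTYPE|cDNA_position|SIFT|PolyPhen">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
    chr1\t100\t.\tC\tT\t.\tPASS\tCSQ=T|missense_variant|GENEA|TR1|protein_coding|50/1000|tolerated(0.32)|benign(0.1),T|missense_variant|GENEA|TR2|protein_coding|60/2000|deleterious(0.01)|probably_damaging(0.95)\tGT\t0/0\t0/1
    chr1\t200\t.\tG\tA\t.\tPASS\tCSQ=A|synonymous_variant|GENEA|TR1|protein_coding|70/1000||\tGT\t0/1\t0/1
    chr1\t300\t.\tAT\tA\t.\tPASS\tCSQ=-|frameshift_variant|GENEB|TR3|protein_coding|80/500||\tGT\t0/0\t0/1
    chr1\t400\t.\tA\tG\t.\tPASS\tCSQ=G|missense_variant|GENEC|TR4|lincRNA|10/300||\tGT\t./.\t0/1
    """)


@pytest.fixture()
def micro_vcf(tmp_path) -> Path:
    path = tmp_path / "micro.vcf"
    path.write_text(MICRO_VCF)
    return path
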