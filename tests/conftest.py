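"""Shared fixtures: synthetic experiment bundles and independent oracles."""

from __future__ import annotations

import pytest

from capscreen.filter_cascade import CascadeThresholds
from capscreen.pileup_depth import build_pileup
from capscreen.synthetic_data import ExperimentBundle, SimConfig, generate_experiment
from capscreen.variant_calling import call_variants, detect_indels

# Error-free high-depth conditions for exact truth-oracle comparisons: at 120x
# the binomial chance that a balanced heterozygote fails the DS>=50 filter is
# below 1e-4, so exact set equality against the logical truth oracle is a fair
# expectation; a duplicated decoy block exists on each chromosome.
ORACLE_CONDITIONS = dict(
    mean_depth=120.0,
    base_error_rate=0.0,
    depth_dispersion=0.0,
    duplicated_locus_fraction=0.5,
)


@pytest.fixture(scope="session")
def oracle_bundle() -> ExperimentBundle:
    return generate_experiment(SimConfig(seed=11, **ORACLE_CONDITIONS))


def calls_for(bundle: ExperimentBundle, reads, sample: str):
    pileup = build_pileup(reads, bundle.regions, bundle.reference)
    return call_variants(pileup, sample=sample) + detect_indels(
        reads, bundle.regions, bundle.reference, sample=sample
    )


@pytest.fixture(scope="session")
def oracle_calls(oracle_bundle):
    """Raw per-sample and pooled-control calls for the oracle bundle."""
    member_calls = {
        s: calls_for(oracle_bundle, reads, s)
        for s, reads in oracle_bundle.sample_reads.items()
    }
    control_calls = calls_for(oracle_bundle, oracle_bundle.control_pool_reads, "control_pool")
    return member_calls, control_calls


@pytest.fixture(scope="session")
def recall_run():
    """Error-free 30x single-carrier experiment with 120 planted het SNPs."""
    from capscreen.io_formats import FamilySpec
    from capscreen.variant_calling import call_variants

    config = SimConfig(
        seed=23,
        n_chromosomes=1,
        chrom_length=12_000,
        n_target_regions=8,
        families=(FamilySpec("F1", ("S1",), "chr1"),),
        mean_depth=30.0,
        depth_dispersion=0.0,
        base_error_rate=0.0,
        n_controls=0,
        duplicated_locus_fraction=0.0,
        plant_decoys=False,
        plant_truncating=False,
        plant_indels=False,
        n_extra_het_snps=119,
    )
    bundle = generate_experiment(config)
    pileup = build_pileup(bundle.sample_reads["S1"], bundle.regions, bundle.reference)
    calls = {c.key: c for c in call_variants(pileup)}
    truth = [t for t in bundle.truth if "S1" in t.carriers and t.kind == "SNP"]
    return truth, calls


# ---------------------------------------------------------------------------
# independent read-walking oracle (kept deliberately naive)


def naive_aligned_pairs(read):
    """(ref_pos, base, qual) triples for one placement, by direct enumeration."""
    pairs = []
    g = read.gap
    if g is None:
        for i, b in enumerate(read.bases):
            pairs.append((read.pos + i, b, read.quals[i]))
    elif g.kind == "DEL":
        for i in range(g.offset):
            pairs.append((read.pos + i, read.bases[i], read.quals[i]))
        for i in range(g.offset, len(read.bases)):
            pairs.append((read.pos + g.length + i, read.bases[i], read.quals[i]))
    else:
        for i in range(g.offset):
            pairs.append((read.pos + i, read.bases[i], read.quals[i]))
        for i in range(g.offset + g.length, len(read.bases)):
            pairs.append((read.pos + i - g.length, read.bases[i], read.quals[i]))
    return pairs
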