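import numpy as np
import pandas as pd
import pytest

from triomut.calling import FamilyLayout
from triomut.simulate import SimulationConfig, simulate_trio


@pytest.fixture(scope="session")
def dense_family():
    """A small dense-mode family with a high mutation rate for call tests."""
    config = SimulationConfig(
        genome_length=50_000,
        n_chromosomes=2,
        n_offspring=5,
        mu_true=2e-5,
        seq_error_rate=1e-3,
        seed=1,
    )
    return simulate_trio(config)


@pytest.fixture(scope="session")
def clean_family():
    """Error-free, saturating-depth family: every truth DNM is recoverable."""
    config = SimulationConfig(
        genome_length=60_000,
        n_chromosomes=2,
        n_offspring=5,
        mu_true=2e-5,
        mean_depth=150.0,
        seq_error_rate=0.0,
        low_mq_fraction=0.0,
        low_quality_fraction=0.0,
        multi_nonref_fraction=0.0,
        seed=7,
    )
    return simulate_trio(config)


@pytest.fixture
def trio_layout():
    return FamilyLayout("father", "mother", ("o01", "o02", "o03"))


def make_site_row(
    layout,
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    mq=45,
    low_quality=False,
    max_nonref_per_read=1,
    region="intergenic",
    in_cpg=False,
    **overrides,
):
    """One wide site-table row with benign defaults for every sample.

    Per-sample values are overridden with keys like ``GT_o01`` or
    ``DP_father``.
    """
    row = {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "mq": mq,
        "low_quality": low_quality,
        "max_nonref_per_read": max_nonref_per_read,
        "region": region,
        "in_cpg": in_cpg,
    }
    for s in layout.samples:
        row[f"GT_{s}"] = "0/0"
        row[f"DP_{s}"] = 30
        row[f"AD_{s}"] = 0
    row.update(overrides)
    return row


def make_site_table(layout, rows):
    return pd.DataFrame([make_site_row(layout, **r) for r in rows])


@pytest.fixture
def site_row_factory(trio_layout):
    def factory(**kwargs):
        return make_site_row(trio_layout, **kwargs)

    return factory


def random_site_table(layout, n_rows, seed):
    """Random candidate-site table exercising every filter branch."""
    rng = np.random.default_rng(seed)
    rows = []
    bases = "ACGT"
    for i in range(n_rows):
        ref = bases[rng.integers(0, 4)]
        alt = [b for b in bases if b != ref][rng.integers(0, 3)]
        row = {
            "chrom": f"chr{1 + rng.integers(0, 2)}",
            "pos": i + 1,
            "ref": ref,
            "alt": alt,
            "mq": int(rng.integers(0, 61)),
            "low_quality": bool(rng.random() < 0.1),
            "max_nonref_per_read": int(rng.integers(0, 5)),
            "region": "gene" if rng.random() < 0.4 else "intergenic",
            "in_cpg": bool(rng.random() < 0.1),
        }
        n_carriers = rng.choice([0, 1, 1, 1, 2, 3])
        carriers = set(rng.choice(len(layout.offspring), size=n_carriers, replace=False))
        for s in layout.parents:
            dp = int(rng.integers(0, 40))
            row[f"GT_{s}"] = "0/1" if rng.random() < 0.05 else "0/0"
            row[f"DP_{s}"] = dp
            row[f"AD_{s}"] = int(rng.integers(0, dp + 1)) if rng.random() < 0.1 else 0
        for j, s in enumerate(layout.offspring):
            dp = int(rng.integers(0, 40))
            if j in carriers:
                gt = "0/1" if rng.random() < 0.8 else "1/1"
                ad = int(rng.integers(0, dp + 1))
            else:
                gt = "0/0"
                ad = 0
            row[f"GT_{s}"] = gt
            row[f"DP_{s}"] = dp
            row[f"AD_{s}"] = ad
        rows.append(row)
    return pd.DataFrame(rows)
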