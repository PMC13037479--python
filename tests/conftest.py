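import numpy as np
import pytest

from viroturn import LineageSpec, SortedLibrary, SyntheticCommunitySpec


@pytest.fixture
def three_lineage_spec():
    """Three viral lineages with distinct turnover, sorted at the study depths."""

    def _make(seed=1, contig_yield=0.01, **overrides):
        kwargs = dict(
            lineages=[
                LineageSpec("lin_hi", "viral", 1 / 3, turnover_theta=0.9),
                LineageSpec("lin_mid", "viral", 1 / 3, turnover_theta=0.5),
                LineageSpec("lin_lo", "viral", 1 / 3, turnover_theta=0.1),
            ],
            libraries=[
                SortedLibrary("vp", "viral_progeny", 100_000),
                SortedLibrary("vi", "pre_existing_viruses", 50_000),
            ],
            contig_yield=contig_yield,
            seed=seed,
        )
        kwargs.update(overrides)
        return SyntheticCommunitySpec(**kwargs)

    return _make


@pytest.fixture
def four_fraction_spec():
    """Two viral + two host lineages across all four sorted fractions."""

    def _make(seed=3, **overrides):
        kwargs = dict(
            lineages=[
                LineageSpec("vA", "viral", 0.6, turnover_theta=0.7, infection_link="hA"),
                LineageSpec("vB", "viral", 0.4, turnover_theta=0.3, infection_link="hB"),
                LineageSpec("hA", "host", 0.5, activity_prob=0.8),
                LineageSpec("hB", "host", 0.5, activity_prob=0.2),
            ],
            libraries=[
                SortedLibrary("vp", "viral_progeny", 2000),
                SortedLibrary("vi", "pre_existing_viruses", 1000),
                SortedLibrary("ca", "active_cells", 500),
                SortedLibrary("ci", "inactive_cells", 500),
            ],
            seed=seed,
        )
        kwargs.update(overrides)
        return SyntheticCommunitySpec(**kwargs)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
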