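"""Shared fixtures: synthetic datasets and derived pipeline objects.

Heavy objects are session-scoped so the end-to-end chain (annotation ->
catalog -> views -> DE -> networks -> signature) is computed once.
"""

import numpy as np
import pytest

from lncsig.annotation import build_catalog, mrna_universe, parse_netaffx
from lncsig.coexpression import build_network
from lncsig.diffexp import differential_expression
from lncsig.expression import Contrast, split_by_catalog
from lncsig.synth import SyntheticDesign, simulate_annotation, simulate_expression

CONTRASTS = (
    Contrast("PM_vs_N", "PM", "N"),
    Contrast("MM_vs_N", "MM", "N"),
    Contrast("MM_vs_PM", "MM", "PM"),
)
R_CUTOFFS = {"PM_vs_N": 0.80, "MM_vs_N": 0.90, "MM_vs_PM": 0.80}


@pytest.fixture(scope="session")
def design():
    return SyntheticDesign(seed=17)


@pytest.fixture(scope="session")
def annotation_bundle(design):
    """(records, truth) from the default synthetic annotation table."""
    text, truth = simulate_annotation(design, np.random.default_rng(17))
    return parse_netaffx(text), truth


@pytest.fixture(scope="session")
def catalog(annotation_bundle):
    records, _ = annotation_bundle
    return build_catalog(records)


@pytest.fixture(scope="session")
def expression_bundle(design):
    """(ExpressionMatrix, truth) from the default synthetic design."""
    return simulate_expression(design, np.random.default_rng(23))


@pytest.fixture(scope="session")
def views(expression_bundle, annotation_bundle, catalog):
    records, _ = annotation_bundle
    matrix, _ = expression_bundle
    return split_by_catalog(matrix, catalog, mrna_universe(records, catalog))


@pytest.fixture(scope="session")
def de_results(views):
    """{contrast: {molecule: ComparisonResult}} over the three contrasts."""
    lnc_view, mrna_view = views
    results = {}
    for contrast in CONTRASTS:
        results[contrast.name] = {
            "lncRNA": differential_expression(lnc_view, contrast, "lncRNA"),
            "mRNA": differential_expression(mrna_view, contrast, "mRNA"),
        }
    return results


@pytest.fixture(scope="session")
def networks(de_results, expression_bundle):
    matrix, _ = expression_bundle
    return {
        name: build_network(
            results["lncRNA"], results["mRNA"], matrix, r_cutoff=R_CUTOFFS[name]
        )
        for name, results in de_results.items()
    }
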