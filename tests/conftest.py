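"""Shared fixtures: phantom cases, a phantom-built repository, and the
end-to-end charting runs reused across test modules (they are the
expensive part of the suite, so they are session-scoped)."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from dentalchart import cli, masks, phantom
from dentalchart.repository import Repository, build_repository

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: Seeds for the repository-building cases and the cases charted against it.
REPO_SEEDS = (101, 102, 103)
CASE_SEED = 7
JITTER_SEEDS = (8, 9)


def case_polyline(pi: phantom.PhantomImage):
    """Gold CEJ polyline(s) for a phantom image, via the mask-connection op."""
    lines = cli._cej_polylines(masks.Mask(pi.cej_mask, kind="cej"))
    if pi.kind == "bitewing":
        lines = sorted(lines, key=lambda l: l.mean_row)
        return (lines[0], lines[1])
    return lines[0]


def repo_from_seeds(seeds) -> Repository:
    """Repository built from phantom panoramics, using each gold box's
    corners as the annotation polygon."""
    panoramics = []
    for s in seeds:
        pan = phantom.generate_phantom_case(phantom.PhantomConfig(seed=s)).panoramic
        anns = [{"polygon": [[t.box[0], t.box[1]], [t.box[2] - 1, t.box[1]],
                             [t.box[2] - 1, t.box[3] - 1], [t.box[0], t.box[3] - 1]],
                 "fdi": t.fdi} for t in pan.teeth]
        panoramics.append((pan.image, anns, f"seed{s}"))
    return build_repository(panoramics)


@pytest.fixture(scope="session")
def no_jitter_case() -> phantom.PhantomCase:
    return phantom.generate_phantom_case(phantom.PhantomConfig(seed=CASE_SEED))


@pytest.fixture(scope="session")
def phantom_repo() -> Repository:
    return repo_from_seeds(REPO_SEEDS)


@pytest.fixture(scope="session")
def many_cases() -> list[phantom.PhantomCase]:
    """Six additional no-jitter cases (>= 100 intraoral images in total)."""
    return [phantom.generate_phantom_case(phantom.PhantomConfig(seed=s))
            for s in range(30, 36)]


@pytest.fixture(scope="session")
def repo_run(no_jitter_case, phantom_repo) -> cli.CaseResult:
    """Repository-mode charting of the no-jitter case."""
    cfg = cli.RunConfig(mode="repository")
    return cli.chart_case(no_jitter_case, cfg, repo=phantom_repo)


@pytest.fixture(scope="session")
def jitter_runs(phantom_repo) -> list[cli.CaseResult]:
    """Repository-mode charting of two 10%-scale-jitter cases."""
    cfg = cli.RunConfig(mode="repository")
    results = []
    for s in JITTER_SEEDS:
        case = phantom.generate_phantom_case(
            phantom.PhantomConfig(seed=s, scale_jitter=0.10))
        results.append(cli.chart_case(case, cfg, repo=phantom_repo))
    return results
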