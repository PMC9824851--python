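import pytest

import padelql as pql
from padelql import ingest as ing


@pytest.fixture(scope="session")
def fixture_tables():
    return pql.make_fixture_tables()


@pytest.fixture(scope="session")
def fixture_records(fixture_tables):
    points_df, shots_df, frames_df = fixture_tables
    return (ing.read_points(points_df), ing.read_shots(shots_df),
            ing.read_frames(frames_df))


@pytest.fixture(scope="session")
def fixture_match(fixture_records):
    points, shots, frames = fixture_records
    cfg = ing.IngestConfig(title="worked example",
                           video_url="https://video.example/match?v=abc")
    return ing.assemble_match(points, shots, frames, cfg)


def assemble_bundle(bundle, video_url="https://video.example/m"):
    """Run a generated bundle through the full ingest path."""
    cfg = ing.IngestConfig(fps=bundle.config.fps, title="synthetic",
                           video_url=video_url,
                           scoring_mode=bundle.config.scoring_mode)
    return ing.assemble_match(
        ing.read_points(bundle.points.astype(str)),
        ing.read_shots(bundle.shots.astype(str)),
        ing.read_frames(bundle.frames.astype(str)), cfg)


@pytest.fixture(scope="session")
def synth_bundle():
    return pql.generate_match(pql.SynthConfig(seed=7, max_points=12))


@pytest.fixture(scope="session")
def synth_match(synth_bundle):
    return assemble_bundle(synth_bundle)


@pytest.fixture(scope="session")
def small_corpus():
    """A handful of (bundle, match) pairs for sweep-style unit tests."""
    out = []
    for seed in (1, 2, 3, 4, 5):
        bundle = pql.generate_match(pql.SynthConfig(seed=seed, max_points=6))
        out.append((bundle, assemble_bundle(bundle)))
    return out
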