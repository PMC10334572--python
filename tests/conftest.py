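import pytest

from eggrisk import SyntheticSurveyConfig, generate_survey


@pytest.fixture
def make_survey_csv(tmp_path):
    """Factory writing a survey CSV from raw row strings."""

    def _make(rows, header="brand,season,replicate,metal,conc_ugkg", name="survey.csv"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return _make


@pytest.fixture
def default_survey():
    """One seeded synthetic survey at the default design and moments."""
    records, truth = generate_survey(SyntheticSurveyConfig(seed=7))
    return records, truth
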