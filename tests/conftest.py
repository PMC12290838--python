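import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def synthetic_input_dir(tmp_path):
    """A complete synthetic input directory written through the CLI."""
    from click.testing import CliRunner

    from xenocall.cli import main

    runner = CliRunner()
    out = tmp_path / "inputs"
    result = runner.invoke(main, ["simulate", "--seed", "42", "--out", str(out)])
    assert result.exit_code == 0, result.output
    return out
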