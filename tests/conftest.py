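import numpy as np
import pytest

from cdr3err.extract import FlankSpec, extract_all
from cdr3err.simulate import ErrorModel, example_template, simulate_reads


@pytest.fixture(scope="session")
def template36():
    return example_template(36)


@pytest.fixture(scope="session")
def template30():
    return example_template(30)


@pytest.fixture(scope="session")
def flanks36(template36):
    return FlankSpec.from_template(template36)


@pytest.fixture(scope="session")
def zero_error_model():
    return ErrorModel(sub_rate=0.0)


@pytest.fixture(scope="session")
def noisy_mono_run(template36, flanks36):
    """A moderate monoclonal run with uniform CDR3-only errors and indels.

    Errors are confined to the CDR3 window so nearly every read passes flank
    matching; the quality model ties low scores to error bases.
    """
    model = cdr3_only_model(template36, rate=2e-3, del_rate=2e-4, ins_rate=1e-4)
    reads, truth = simulate_reads(template36, model, 20_000, n_lanes=3, seed=101)
    records, rejections = extract_all(reads, flanks36)
    return {
        "template": template36,
        "model": model,
        "reads": reads,
        "truth": truth,
        "records": records,
        "rejections": rejections,
    }


def cdr3_only_model(template, rate, **kwargs) -> ErrorModel:
    """Uniform per-(position, alternative) rate inside the CDR3 window, zero elsewhere."""
    m = np.zeros((len(template), 4))
    m[template.cdr3_start : template.cdr3_end] = rate
    return ErrorModel(sub_rate=m, **kwargs)


def truth_cdr3_errors(errors_token: str, template) -> list[tuple[int, str, str]]:
    """Parse a SimTruth errors field into CDR3-window coordinates."""
    out = []
    if not errors_token:
        return out
    for tok in errors_token.split(";"):
        pos, rest = tok.split(":")
        fr, to = rest.split(">")
        pos = int(pos)
        if template.cdr3_start <= pos < template.cdr3_end:
            out.append((pos - template.cdr3_start, fr, to))
    return out
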