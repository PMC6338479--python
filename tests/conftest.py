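import random

import pytest

from bcokit import forge
from bcokit.model import FileRef, IoDomain, PipelineStep


@pytest.fixture
def minimal_env():
    """Fresh copy of the minimal complete valid BCO fixture."""
    return forge.forge_minimal_envelope()


@pytest.fixture(scope="session")
def toy_kit(tmp_path_factory):
    """Error-free toy verification kit forged once per session (seed 42)."""
    kit_dir = tmp_path_factory.mktemp("toykit")
    env, case = forge.forge_toy_bco(42, kit_dir)
    return env, case, kit_dir


def random_step_graph(rng: random.Random, max_steps: int = 8,
                      max_files: int = 4):
    """Random pipeline-step graph (possibly violating dataflow closure).

    URIs are drawn from a small pool so that both satisfied and violated
    input references arise.
    """
    pool = [f"u{i}" for i in range(10)]
    n = rng.randint(1, max_steps)
    steps = [
        PipelineStep(
            number=k,
            name=f"s{k}",
            inputs=[FileRef(uri=u) for u in
                    rng.sample(pool, k=rng.randint(0, max_files))],
            outputs=[FileRef(uri=u) for u in
                     rng.sample(pool, k=rng.randint(0, max_files))])
        for k in range(1, n + 1)
    ]
    io = IoDomain(inputs=[FileRef(uri=u) for u in
                          rng.sample(pool, k=rng.randint(0, 3))])
    return steps, io


def dataflow_oracle(steps, io):
    """Brute-force prior-outputs oracle: a step input is violating iff it is
    not in io.inputs nor among the outputs of any strictly earlier step."""
    external = {f.uri for f in io.inputs}
    violations = []
    ordered = sorted(steps, key=lambda s: s.number)
    for step in ordered:
        earlier = {o.uri for s in ordered if s.number < step.number
                   for o in s.outputs}
        for inp in step.inputs:
            if inp.uri not in external and inp.uri not in earlier:
                violations.append((step.number, inp.uri))
    return violations
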