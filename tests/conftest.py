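import pytest

from oab_cea import paper_basecase
from oab_cea.engine import Occupancy, OccupancyTrajectory
from oab_cea.parameters import ParameterSet


@pytest.fixture(scope="session")
def basecase() -> ParameterSet:
    return paper_basecase()


def _key(node: dict, part: str):
    if part not in node and part.isdigit() and int(part) in node:
        return int(part)
    return part


def deep_update(doc: dict, path: str, value) -> dict:
    """Set a dotted path in a nested dict (helper for perturbed copies)."""
    parts = path.split(".")
    node = doc
    for part in parts[:-1]:
        node = node[_key(node, part)]
    node[_key(node, parts[-1])] = value
    return doc


def modified(params: ParameterSet, **dotted) -> ParameterSet:
    """A re-validated copy of ``params`` with dotted-path overrides."""
    from oab_cea.parameters import parameter_set_from_internal

    doc = params.model_dump()
    for path, value in dotted.items():
        deep_update(doc, path.replace("__", "."), value)
    return parameter_set_from_internal(doc)


def uniform_trajectory(arm_id: str, dose: str, continent: float,
                       incontinent: float) -> OccupancyTrajectory:
    """A trajectory with identical occupancy at every checkpoint."""
    occ = Occupancy(
        continent_on_rx={dose: continent} if continent else {},
        incontinent_on_rx={dose: incontinent} if incontinent else {},
        untreated=1.0 - continent - incontinent,
    )
    return OccupancyTrajectory(
        arm_id=arm_id,
        checkpoints={week: occ for week in (8, 12, 24, 52)},
        response_w12=continent,
    )
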