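import pytest

from dpcrtools import ChipDesign, ConfidenceSpec, PartitionCounts
from dpcrtools.pipeline import ChipRecord


@pytest.fixture
def paper_spec() -> ConfidenceSpec:
    """95% confidence with Z pinned to the conventional 1.96."""
    return ConfidenceSpec(strict_paper=True)


def make_record(
    sample: str,
    chip: str,
    concentration: float,
    dilution: float = 1.0,
    n: int = 10000,
    volume: float = 1e-3,
    is_ntc: bool = False,
    flag: str = "green",
    positives: int | None = None,
) -> ChipRecord:
    """Build a ChipRecord whose counts reproduce a target measured concentration.

    Negatives are set to round(n·e^{−C·V}), so the estimated concentration
    matches ``concentration`` to rounding accuracy; an explicit ``positives``
    count overrides this.
    """
    import math

    lam = concentration * volume
    negatives = round(n * math.exp(-lam)) if positives is None else n - positives
    return ChipRecord(
        sample_id=sample,
        chip_id=chip,
        dilution_factor=dilution,
        counts=PartitionCounts(n=n, negatives=negatives),
        design=ChipDesign(n=n, partition_volume=volume),
        is_ntc=is_ntc,
        quality_flag=flag,
    )
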