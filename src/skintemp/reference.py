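"""Fixed-weight reference composites T_PROX and T_DIST.

The proximal composite weighs the abdomen 0.324, each infra-clavicular site
0.1465 and each mid-thigh site 0.1915; the distal composite averages the
four hand/foot sites with weight 0.25 each.  Both weight sets sum to 1, so
each composite is a convex combination of its sensors.
"""

from __future__ import annotations

import numpy as np

from .containers import SubjectRecording, TemperatureSeries
from .errors import MissingSiteError
from .sites import GROUP_SITES, SiteCode, SiteGroup

#: Fixed composite weights (stored as exact decimal constants; no renormalization).
REFERENCE_WEIGHTS: dict[SiteGroup, dict[SiteCode, float]] = {
    SiteGroup.PROX: {
        SiteCode.A: 0.324,
        SiteCode.LIA: 0.1465,
        SiteCode.RIA: 0.1465,
        SiteCode.LMT: 0.1915,
        SiteCode.RMT: 0.1915,
    },
    SiteGroup.DIST: {
        SiteCode.LF: 0.25,
        SiteCode.RF: 0.25,
        SiteCode.LH: 0.25,
        SiteCode.RH: 0.25,
    },
}

COMPOSITE_LABEL = {SiteGroup.PROX: "T_PROX", SiteGroup.DIST: "T_DIST"}


def compute_reference(recording: SubjectRecording, group: SiteGroup) -> TemperatureSeries:
    """Per-instant weighted sum over the full sensor set of ``group``.

    The output is valid exactly where *all* group sensors are valid.  A
    missing sensor raises :class:`MissingSiteError` — the reference is
    undefined on reduced sets (re-tuned weights handle those).
    """
    recording.assert_common_grid()
    for site in GROUP_SITES[group]:
        if site not in recording:
            raise MissingSiteError(site, f"reference {COMPOSITE_LABEL[group]}")
    weights = REFERENCE_WEIGHTS[group]
    template = recording[GROUP_SITES[group][0]]
    values = np.zeros(len(template))
    for site, w in weights.items():
        values += w * recording[site].values
    mask = recording.group_valid_mask(group)
    return TemperatureSeries(
        site=COMPOSITE_LABEL[group],
        start_time=template.start_time,
        sampling_interval_min=template.sampling_interval_min,
        values=values,
        valid_mask=mask,
    )
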