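"""Default 30-node large-scale network atlas.

Node labels follow the naming of ICA-derived cortical network atlases:
eight classical networks, with the cerebellar nodes excluded for coverage
reasons, leaving 30 cortical regions of interest.  The pipeline treats the
nodes as an undifferentiated whole-brain graph; the network labels exist
only for readable output.
"""

from __future__ import annotations

# network -> ROI labels
NETWORKS: dict[str, list[str]] = {
    "DMN": ["DMN.MPFC", "DMN.LP_l", "DMN.LP_r", "DMN.PCC"],
    "SensoriMotor": ["SM.Lateral_l", "SM.Lateral_r", "SM.Superior"],
    "Visual": ["Vis.Medial", "Vis.Occipital", "Vis.Lateral_l", "Vis.Lateral_r"],
    "Salience": [
        "SN.ACC",
        "SN.AInsula_l",
        "SN.AInsula_r",
        "SN.RPFC_l",
        "SN.RPFC_r",
        "SN.SMG_l",
        "SN.SMG_r",
    ],
    "DorsalAttention": ["DAN.FEF_l", "DAN.FEF_r", "DAN.IPS_l", "DAN.IPS_r"],
    "FrontoParietal": ["FPN.LPFC_l", "FPN.LPFC_r", "FPN.PPC_l", "FPN.PPC_r"],
    "Language": ["Lang.IFG_l", "Lang.IFG_r", "Lang.pSTG_l", "Lang.pSTG_r"],
}

NODE_LABELS: list[str] = [roi for rois in NETWORKS.values() for roi in rois]
N_NODES: int = len(NODE_LABELS)

assert N_NODES == 30

#: 4-edge star used as the default ground-truth component: the medial
#: prefrontal hub connected to bilateral anterior insula and bilateral
#: lateral prefrontal cortex (the canonical self-prioritization topology).
DEFAULT_STAR_EDGES: list[tuple[int, int]] = [
    (NODE_LABELS.index("DMN.MPFC"), NODE_LABELS.index("SN.AInsula_l")),
    (NODE_LABELS.index("DMN.MPFC"), NODE_LABELS.index("SN.AInsula_r")),
    (NODE_LABELS.index("DMN.MPFC"), NODE_LABELS.index("FPN.LPFC_l")),
    (NODE_LABELS.index("DMN.MPFC"), NODE_LABELS.index("FPN.LPFC_r")),
]
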