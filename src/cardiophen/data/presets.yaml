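# Printed group means from the HADHA/MiMaC hiPSC-CM study, organised by
# modality.  Every value is a number printed in a figure caption or methods
# sentence; nothing here is interpolated from plotted data.
calcium:
  WT_12D_GlcFA:
    source: "Fig. 4e/4f captions (WT CM after 12 d Glc+FA)"
    parameters:
      fold: {value: 2.03, units: "F/F0"}
      tau: {value: 0.63, units: "s"}
  Mut_12D_GlcFA:
    source: "Fig. 4e/4f captions (HADHA Mut CM after 12 d Glc+FA)"
    parameters:
      fold: {value: 1.55, units: "F/F0"}
      tau: {value: 0.76, units: "s"}

patch:
  WT_12D_GlcFA:
    source: "Fig. 4h caption (WT CM APD90)"
    parameters:
      apd90: {value: 541.0, units: "ms"}
  Mut_12D_GlcFA:
    source: "Fig. 4h caption (HADHA Mut CM APD90)"
    parameters:
      apd90: {value: 1068.0, units: "ms"}

rhythm:
  Mut_Glc:
    source: "Results, beat-rate-variability analysis (Poincare ellipse ratio, Glc)"
    parameters:
      axis_ratio: {value: 4.36, units: "dimensionless"}
  Mut_GlcFA:
    source: "Results, beat-rate-variability analysis (Poincare ellipse ratio, Glc+FA)"
    parameters:
      axis_ratio: {value: 3.12, units: "dimensionless"}

micropost:
  EV:
    source: "Fig. 3b/3d captions (empty-vector control hiPSC-CM)"
    parameters:
      twitch_force: {value: 24.0, units: "nN"}
      power: {value: 22.0, units: "fW"}
  MiMaC:
    source: "Fig. 3b/3d captions (MiMaC-treated hiPSC-CM)"
    parameters:
      twitch_force: {value: 36.0, units: "nN"}
      power: {value: 38.0, units: "fW"}

mitostress:
  WT_12D_GlcFA:
    source: "Fig. 6g/6h/6i captions (WT CM after 12 d Glc+FA)"
    parameters:
      max_ocr: {value: 359.0, units: "pmol/min/cell"}
      atp_production: {value: 93.0, units: "pmol/min/cell"}
      proton_leak: {value: 3.64, units: "pmol/min/cell"}
  Mut_12D_GlcFA:
    source: "Fig. 6g/6h/6i captions (HADHA Mut CM after 12 d Glc+FA)"
    parameters:
      max_ocr: {value: 190.0, units: "pmol/min/cell"}
      atp_production: {value: 51.0, units: "pmol/min/cell"}
      proton_leak: {value: 7.66, units: "pmol/min/cell"}
  KO_12D_GlcFA:
    source: "Fig. 6g/6h/6i captions (HADHA KO CM after 12 d Glc+FA)"
    parameters:
      max_ocr: {value: 125.0, units: "pmol/min/cell"}
      atp_production: {value: 43.0, units: "pmol/min/cell"}
      proton_leak: {value: 10.52, units: "pmol/min/cell"}

area:
  EV:
    source: "Fig. 3e caption (empty-vector control cell area)"
    parameters:
      cell_area: {value: 2389.0, units: "um^2"}
  MiMaC:
    source: "Fig. 3e caption (MiMaC-treated cell area)"
    parameters:
      cell_area: {value: 3022.0, units: "um^2"}
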