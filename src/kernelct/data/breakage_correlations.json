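{
  "note": "Published correlations of each structural parameter with breakage rate, keyed by the figure's letter codes. Two entries (H and K) carry the same label in the source; both are kept verbatim.",
  "entries": [
    {"key": "A", "label": "Density", "r": -0.934, "stars": "**"},
    {"key": "B", "label": "Sphericity", "r": -0.714, "stars": "*"},
    {"key": "C", "label": "The cavity specific surface area", "r": -0.628, "stars": "*"},
    {"key": "D", "label": "Embryo cavity volume ratio", "r": -0.551, "stars": ""},
    {"key": "E", "label": "Embryo cavity volume", "r": -0.436, "stars": ""},
    {"key": "F", "label": "Grain weight", "r": -0.371, "stars": ""},
    {"key": "G", "label": "Cavity surface area", "r": -0.138, "stars": ""},
    {"key": "H", "label": "Endosperm volume ratio", "r": -0.063, "stars": ""},
    {"key": "I", "label": "Endosperm cavity volume", "r": -0.049, "stars": ""},
    {"key": "J", "label": "Embryo volume ratio", "r": -0.015, "stars": ""},
    {"key": "K", "label": "Endosperm volume ratio", "r": -0.014, "stars": ""},
    {"key": "L", "label": "Endosperm volume", "r": -0.004, "stars": ""},
    {"key": "M", "label": "Thickness", "r": 0.001, "stars": ""},
    {"key": "N", "label": "Width", "r": 0.007, "stars": ""},
    {"key": "O", "label": "Embryo volume", "r": 0.011, "stars": ""},
    {"key": "P", "label": "Grain volume", "r": 0.013, "stars": ""},
    {"key": "Q", "label": "Cavity volume", "r": 0.057, "stars": ""},
    {"key": "R", "label": "Aspect ratio", "r": 0.087, "stars": ""},
    {"key": "S", "label": "Cavity volume ratio", "r": 0.209, "stars": ""},
    {"key": "T", "label": "Length", "r": 0.249, "stars": ""},
    {"key": "U", "label": "Endosperm surface area", "r": 0.288, "stars": ""},
    {"key": "V", "label": "The Endosperm specific surface area", "r": 0.308, "stars": ""},
    {"key": "W", "label": "Embryo surface area", "r": 0.374, "stars": ""},
    {"key": "X", "label": "Grain surface area", "r": 0.431, "stars": ""},
    {"key": "Y", "label": "Subcutaneous Cavity volume ratio", "r": 0.581, "stars": "*"},
    {"key": "Z", "label": "Subcutaneous Cavity volume", "r": 0.589, "stars": "*"},
    {"key": "Z1", "label": "Grain specific surface area", "r": 0.758, "stars": "*"},
    {"key": "Z2", "label": "Embryo specific surface area", "r": 0.927, "stars": "**"}
  ]
}
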