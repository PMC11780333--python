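{
 "normal": {
  "A": "#1F77B4",
  "B": "#FF7F0E",
  "het": "#2CA02C",
  "missing": "#D3D3D3"
 },
 "Aqua": {
  "A": "#00B5CC",
  "B": "#F4A261",
  "het": "#7B68AE",
  "missing": "#E8E8E8"
 },
 "mono": {
  "A": "#202020",
  "B": "#B0B0B0",
  "het": "#686868",
  "missing": "#F5F5F5"
 }
}
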