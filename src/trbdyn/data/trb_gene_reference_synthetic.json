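{
  "name": "trb-gene-reference-synthetic",
  "docstring": "Synthetic IMGT-style functionality snapshot for human TRB gene segments. Constructed for this package (not a verbatim IMGT export): 43 functional V genes of which TRBV03-01 is excluded from analysis (leaving the 42-gene analysis set), 13 functional J genes, 2 D genes, and a set of V orphons. Override with your own snapshot via GeneReference.from_json.",
  "functional_v": [
    "TRBV02-01", "TRBV03-01", "TRBV04-01", "TRBV04-02", "TRBV04-03",
    "TRBV05-01", "TRBV05-04", "TRBV05-05", "TRBV05-08",
    "TRBV06-01", "TRBV06-03", "TRBV06-04", "TRBV06-05", "TRBV06-06",
    "TRBV06-08", "TRBV06-09",
    "TRBV07-02", "TRBV07-03", "TRBV07-06", "TRBV07-07", "TRBV07-08", "TRBV07-09",
    "TRBV09-01", "TRBV10-01", "TRBV10-02", "TRBV10-03",
    "TRBV11-01", "TRBV11-02", "TRBV11-03",
    "TRBV12-04", "TRBV12-05", "TRBV13-01", "TRBV14-01", "TRBV15-01",
    "TRBV16-01", "TRBV18-01", "TRBV19-01", "TRBV20-01",
    "TRBV24-01", "TRBV25-01", "TRBV27-01", "TRBV28-01", "TRBV29-01"
  ],
  "functional_j": [
    "TRBJ01-01", "TRBJ01-02", "TRBJ01-03", "TRBJ01-04", "TRBJ01-05", "TRBJ01-06",
    "TRBJ02-01", "TRBJ02-02", "TRBJ02-03", "TRBJ02-04", "TRBJ02-05", "TRBJ02-06",
    "TRBJ02-07"
  ],
  "functional_d": ["TRBD01-01", "TRBD02-01"],
  "orphon_v": [
    "TRBV20/OR9-2", "TRBV21/OR9-2", "TRBV22/OR9-2", "TRBV23/OR9-2",
    "TRBV24/OR9-2", "TRBV25/OR9-2", "TRBV26/OR9-2", "TRBV29/OR9-2"
  ],
  "excluded": ["TRBV03-01"]
}
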