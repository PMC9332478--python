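{
 "sample_metadata.csv": "f7850187ba662149cd9bf2592c76766e3ae4b1c4184ae047082f29dc1dfa2553",
 "compound_catalog.csv": "b9c07f7271cb232a43b774959cf0140e4b293bf5571cde8c58ccd7f3d9ac900a",
 "calibration_curves.csv": "d165038ca03f38c06bfc5985b04a766b8ca31117bcc2d8fb24ba78972729d83e",
 "concentration_matrix.csv": "179a1c0aaf0e5fc0425f50dc517b74e041861ba1f1970d5767dd8bbea17ea406",
 "printed_oav.csv": "8e12191ede43fcea0f44ec94e79b5858e0a5dd8d7bfbd166985a5491794707f5"
}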