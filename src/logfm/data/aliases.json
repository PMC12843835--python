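{
  "version": 1,
  "comment": "Case-insensitive header aliases for descriptor CSV ingestion (ADMETLab-style exports vary). Keys are lower-cased incoming headers, values canonical field names.",
  "id_aliases": ["compound_id", "id", "name", "compound", "no", "no.", "cid", "molecule"],
  "aliases": {
    "mw": "MW",
    "molecular weight": "MW",
    "molweight": "MW",
    "vol": "Vol",
    "volume": "Vol",
    "dense": "Dense",
    "density": "Dense",
    "nha": "nHA",
    "nhd": "nHD",
    "nrot": "nRot",
    "nring": "nRing",
    "maxring": "MaxRing",
    "nhet": "nHet",
    "nrig": "nRig",
    "flex": "Flex",
    "fsp3": "Fsp3",
    "tpsa": "TPSA",
    "topopsa": "TPSA",
    "logp": "logP",
    "log p": "logP",
    "logs": "logS",
    "log s": "logS",
    "logd": "logD",
    "logd7.4": "logD",
    "caco2": "caco2",
    "caco-2": "caco2",
    "mdck": "MDCK",
    "pampa": "PAMPA",
    "logvdss": "logVDss",
    "log vdss": "logVDss",
    "vdss": "logVDss",
    "ppb": "PPB",
    "ppb(%)": "PPB",
    "fu": "Fu",
    "fu(%)": "Fu",
    "lipinski": "Lipinski",
    "hmax": "Hmax",
    "aatsc1c": "AATSC1c",
    "zmic1": "ZMIC1",
    "gi_absorption": "GI_absorption",
    "gi absorption": "GI_absorption",
    "logfm": "logFM",
    "log fm": "logFM",
    "logfm_exp": "logFM",
    "smiles": "SMILES"
  }
}
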