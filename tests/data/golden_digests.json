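{
  "outputs": {
    "b_on_w_regressions.tsv": "1ac6c361eddb8dec71aa25611490924d78bc604b746aa623f111e3606664c06a",
    "cohort_summary.tsv": "6204bf7453f2b92c5c1b168ff950c3c80d4e2f1447350c8e8fb54719e267d7b0",
    "colonization.tsv": "780a171680b6ff4c6a21f2e1d68ae44312d77514e0d43ee3f6e55586f5ee95a9",
    "fine_scale.tsv": "b4becb2fc3bfa6cb3fcde51ab63dd545b397f6c8ed70f839c119bafeb882cea7",
    "group_comparisons.tsv": "699e685de452aa6a42959f249a2e7041f7b9f29c733be488fd6f3124b382e8fc",
    "lung_function_fits.tsv": "dcb7e3f0b3db06241b6db18696e8c57e6b68c96a7f5afa0f854533ac0cf0167b",
    "onset.tsv": "d0a89b291874fbbd3c1384d83e0cfdd5f67f74115ad910a903fc9cf70fa7551a",
    "onset_summary.tsv": "ced2fbfe7c36bafd10fbbd2286747d576843acc1d7abc30767e105364669bebb",
    "par_fits.tsv": "47e77f4de629d423935f0141995b1bb5beba240c6c205e53068efe881687e25f",
    "str_fits.tsv": "9909c03acb99e6d54cfff46b2b3264061918a9ccf74018802745c1c7effb34ba"
  }
}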