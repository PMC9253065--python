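{
  "name": "square10",
  "comment": "10x10 open square room, all cells traversable, no rewards.",
  "width": 10,
  "height": 10,
  "rows": [
    "..........",
    "..........",
    "..........",
    "..........",
    "..........",
    "..........",
    "..........",
    "..........",
    "..........",
    ".........."
  ],
  "rewards": {}
}
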