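{
 "format": "pocketvote-qa-weights",
 "version": 1,
 "feature_names": [
  "bdtalign",
  "identity",
  "blosum_rescaled",
  "erld",
  "model_quality"
 ],
 "nets": {
  "mcc": {
   "coefs": [
    [
     [
      -0.407059441036929,
      0.553806024055257,
      0.11807704464261903,
      0.19720587344955015,
      0.4743378831148841,
      0.2924015866970659,
      -0.053177906170789865,
      -0.5427006991811467
     ],
     [
      -0.14431352706736608,
      0.2707881030951906,
      0.2304433091667199,
      0.14213522824851496,
      -0.09731860130613754,
      -0.10988408839820903,
      -0.07579268708746734,
      0.327319897593172
     ],
     [
      -0.17689077775104745,
      0.12334027784680017,
      0.37356581009318435,
      -0.5243827996476979,
      -0.04916490711505338,
      0.47051425427955174,
      -0.05222607831496662,
      0.20933540989615385
     ],
     [
      0.01630938296631362,
      0.24755981348466832,
      0.2989841202623962,
      0.45389857814442636,
      0.5346653941350366,
      0.2796349297485737,
      -0.42711990437427927,
      -0.49485772141304624
     ],
     [
      0.06287997651540081,
      0.11604449165960398,
      -0.05930144538011936,
      0.253027277810792,
      -0.16542836985846424,
      0.022395060680112513,
      0.05135991256377546,
      -0.23420775254094223
     ]
    ],
    [
     [
      -0.4126595422231521
     ],
     [
      0.5127045567927613
     ],
     [
      0.43824820929209196
     ],
     [
      0.8224071567033344
     ],
     [
      0.7247979674689734
     ],
     [
      0.20316663616051558
     ],
     [
      -0.6747434409117494
     ],
     [
      -0.9025092361671478
     ]
    ]
   ],
   "intercepts": [
    [
     0.020372570806646846,
     -0.13616696798841563,
     0.10115513916869716,
     -0.30993991107704805,
     -0.3730081242432606,
     0.17651833482763415,
     0.008815153401119635,
     0.6625496630103244
    ],
    [
     -0.11917070385377568
    ]
   ]
  },
  "bdt": {
   "coefs": [
    [
     [
      -0.6015078048150688,
      0.7958604439076886,
      0.17651193619990038,
      0.3863331334966513,
      0.9161828959168519,
      0.3253481675851845,
      0.01510126042671697,
      -0.7256504678811334
     ],
     [
      -0.0829084642468433,
      0.40152825846479334,
      0.1362989759453754,
      0.1091047774621733,
      0.051050059487775766,
      -0.08863203937667113,
      0.3043410867900721,
      0.34022605115717175
     ],
     [
      -0.2856743938944493,
      0.30032776483360796,
      0.4046947056041305,
      -0.360852805140977,
      0.3234841103093817,
      0.5347836259899472,
      0.01690089627402148,
      -0.06509868318683695
     ],
     [
      -0.24892933445877566,
      0.44959904315694266,
      0.4213420659704215,
      0.6731161282777004,
      1.0606302064686277,
      0.3179771524381803,
      -0.4948319862072424,
      -0.7239787566810649
     ],
     [
      -0.06872511571952594,
      -0.01470988313991014,
      -0.13619990251321487,
      0.16904907306701525,
      -0.11250559475233236,
      -0.13622488000128702,
      -0.027726162838753576,
      -0.10575366674578009
     ]
    ],
    [
     [
      -0.419600911479602
     ],
     [
      0.031508814548814684
     ],
     [
      0.27470555860688683
     ],
     [
      0.5560229728368489
     ],
     [
      1.0036073880398204
     ],
     [
      0.07783980177996964
     ],
     [
      -0.775334302973008
     ],
     [
      -0.7761614517434924
     ]
    ]
   ],
   "intercepts": [
    [
     -0.4715390532302319,
     -0.223908344216858,
     0.23119915360562834,
     0.09385755618178412,
     0.24902958067910264,
     0.0026362875640571657,
     -0.5611872958420293,
     0.06383420943451613
    ],
    [
     -0.22639682620415014
    ]
   ]
  }
 }
}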