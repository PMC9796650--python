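{
 "angle": {
  "bins": 12,
  "cond": {
   "H": [
    0.0005411255411255411,
    0.0021645021645021645,
    0.0005411255411255411,
    0.0005411255411255411,
    0.0010822510822510823,
    0.003246753246753247,
    0.9512987012987013,
    0.02813852813852814,
    0.00487012987012987,
    0.003787878787878788,
    0.003246753246753247,
    0.0005411255411255411
   ],
   "E": [
    0.0014184397163120568,
    0.0028368794326241137,
    0.0014184397163120568,
    0.0028368794326241137,
    0.00425531914893617,
    0.0070921985815602835,
    0.00425531914893617,
    0.00851063829787234,
    0.8851063829787233,
    0.01276595744680851,
    0.06382978723404255,
    0.005673758865248227
   ],
   "C": [
    0.0010570824524312897,
    0.0021141649048625794,
    0.0021141649048625794,
    0.008456659619450317,
    0.015856236786469344,
    0.024312896405919663,
    0.04756871035940803,
    0.08562367864693446,
    0.1649048625792812,
    0.26109936575052856,
    0.2558139534883721,
    0.13107822410147993
   ]
  },
  "ref": [
   0.0008573878250928837,
   0.002286367533581023,
   0.0011431837667905116,
   0.003143755358673907,
   0.005715918833952558,
   0.009717062017719349,
   0.5161474707059159,
   0.03972563589597028,
   0.2254929979994284,
   0.07516433266647614,
   0.08373821091740498,
   0.036867676478994
  ]
 },
 "burial": {
  "edges": [
   0,
   3,
   6,
   9,
   12,
   15,
   18,
   21,
   24,
   27,
   30,
   33,
   100
  ],
  "cond": {
   "h": [
    0.0006297229219143577,
    0.28967254408060455,
    0.18702770780856423,
    0.19080604534005038,
    0.28085642317380355,
    0.03904282115869018,
    0.008816120906801008,
    0.0006297229219143577,
    0.0006297229219143577,
    0.0006297229219143577,
    0.0006297229219143577,
    0.0006297229219143577
   ],
   "p": [
    0.0009487666034155598,
    0.2893738140417457,
    0.18785578747628084,
    0.19165085388994307,
    0.2836812144212524,
    0.03510436432637571,
    0.006641366223908918,
    0.0009487666034155598,
    0.0009487666034155598,
    0.0009487666034155598,
    0.0009487666034155598,
    0.0009487666034155598
   ],
   "c": [
    0.0010672358591248667,
    0.29669156883671294,
    0.1910352187833511,
    0.19637139807897544,
    0.2529348986125934,
    0.044823906083244394,
    0.011739594450373533,
    0.0010672358591248667,
    0.0010672358591248667,
    0.0010672358591248667,
    0.0010672358591248667,
    0.0010672358591248667
   ]
  }
 },
 "sepdist": {
  "dist_edges": [
   0.0,
   2.0,
   4.0,
   6.0,
   8.0,
   10.0,
   12.0,
   14.0,
   16.0
  ],
  "cond": {
   "short": [
    0.0004522158577027434,
    0.002411817907747965,
    0.005728067530901417,
    0.012662044015676817,
    0.027886644558335845,
    0.24871872173650889,
    0.25942116370214047,
    0.44271932469098585
   ],
   "medium": [
    0.0038192234245703373,
    0.010821133036282623,
    0.036282622533418206,
    0.06492679821769573,
    0.13685550604710375,
    0.17377466581795034,
    0.23360916613621896,
    0.33991088478676
   ],
   "long": [
    0.003727865796831314,
    0.010251630941286114,
    0.03727865796831314,
    0.08014911463187326,
    0.13606710158434296,
    0.17148182665424044,
    0.2506989748369059,
    0.3103448275862069
   ]
  }
 },
 "contact": {
  "pair": {
   "cc": 0.06661768307616948,
   "ch": 0.2245897624295861,
   "cp": 0.16042125887827577,
   "hh": 0.20695566985060004,
   "hp": 0.2601028655400441,
   "pp": 0.08131276022532452
  }
 },
 "rsa": {
  "bins": 5,
  "cond": {
   "h": [
    0.25743200506008856,
    0.21695129664769133,
    0.22454142947501582,
    0.28969006957621757,
    0.011385199240986717
   ],
   "p": [
    0.2636103151862464,
    0.218720152817574,
    0.20534861509073543,
    0.29894937917860553,
    0.013371537726838587
   ],
   "c": [
    0.25483870967741934,
    0.2129032258064516,
    0.22688172043010751,
    0.2956989247311828,
    0.00967741935483871
   ]
  }
 },
 "volume": {
  "edges": [
   0,
   2,
   4,
   6,
   8,
   10,
   12,
   100
  ],
  "probs": [
   0.00028169014084507044,
   0.4064788732394366,
   0.10535211267605633,
   0.11098591549295775,
   0.35464788732394364,
   0.019436619718309858,
   0.0028169014084507044
  ]
 }
}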