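# mazetalk task model reference

## Fast-level factors
- location (controllable): centre, left, right, cue
- context: left, right
- query_slot: first, second
- knowledge: knew, did-not-know
- verb: explored, guessed, exploited, waited
- destination: cue, left-arm, right-arm, centre
- syntax: silent, q1-please, q2-explain, q3-which, q4-move, a1-i, a2-knowledge, a3-reward-was, a4-side, a5-so-i, a6-verb, a7-destination

## Outcome modalities
- extero (5 levels): sha256[:16]=3b962c20df68acba
- reward (3 levels): sha256[:16]=df8a0ea81b03cc34
- heard (21 levels): sha256[:16]=4e2bc88ec622824e
- spoken (21 levels): sha256[:16]=be859f3dbd4f2632

## Policies (first move, second move)
- 0: (centre, centre)
- 1: (centre, left)
- 2: (centre, right)
- 3: (centre, cue)
- 4: (left, left)
- 5: (right, right)
- 6: (cue, centre)
- 7: (cue, left)
- 8: (cue, right)
- 9: (cue, cue)

## Location transitions (next <- prev under action)
- go-centre : centre -> centre
- go-centre : left -> left
- go-centre : right -> right
- go-centre : cue -> centre
- go-left : centre -> left
- go-left : left -> left
- go-left : right -> right
- go-left : cue -> left
- go-right : centre -> right
- go-right : left -> left
- go-right : right -> right
- go-right : cue -> right
- go-cue : centre -> cue
- go-cue : left -> left
- go-cue : right -> right
- go-cue : cue -> cue

## Syntax chain
- silent -> silent
- q1-please -> q2-explain
- q2-explain -> q3-which
- q3-which -> q4-move
- q4-move -> q4-move
- a1-i -> a2-knowledge
- a2-knowledge -> a3-reward-was
- a3-reward-was -> a4-side
- a4-side -> a5-so-i
- a5-so-i -> a6-verb
- a6-verb -> a7-destination
- a7-destination -> a7-destination

## Preferences (log)
- extero: [-1.  0.  0.  0.  0.]
- reward: [ 0.  3. -6.]
- heard: flat (all zero)
- spoken: flat (all zero)

## Slow-level factors
- narrative: solve, query, answer
- first_move: centre, left, right, cue
- second_move: centre, left, right, cue
- reward: left, right
- query: first, second

## Narrative transitions
- solve -> query
- query -> answer
- answer -> answer

## Semantic link rule (queried move, reward side) -> slots
- (centre, left) -> (did-not-know, waited, centre)
- (centre, right) -> (did-not-know, waited, centre)
- (left, left) -> (knew, exploited, left-arm)
- (left, right) -> (did-not-know, guessed, left-arm)
- (right, left) -> (did-not-know, guessed, right-arm)
- (right, right) -> (knew, exploited, right-arm)
- (cue, left) -> (did-not-know, explored, cue)
- (cue, right) -> (did-not-know, explored, cue)
- link confidence: 0.9
- policy bias concentration kappa: 2.0

## Link table checksums
- location: sha256[:16]=53c57961973aec3d
- context: sha256[:16]=1a2f8887248c9f29
- query_slot: sha256[:16]=ec0051e4e63d8222
- knowledge: sha256[:16]=abec11159fa31627
- verb: sha256[:16]=0c948bbb62327818
- destination: sha256[:16]=a518b0afd4c66bff
- syntax: sha256[:16]=4f479a3e68181368
- policy link: sha256[:16]=1bb7c79960b2f2c8
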